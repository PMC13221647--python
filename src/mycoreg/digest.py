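"""In-silico tryptic digestion and the emPAI spectral abundance index.

The exponentially modified protein abundance index (emPAI) estimates absolute
protein amount in an LC-MS/MS run from peptide counts alone::

    PAI   = N_observed / N_observable
    emPAI = 10**PAI - 1

where ``N_observed`` is the number of distinct peptides identified for the
protein and ``N_observable`` the number of theoretically observable tryptic
peptides given the instrument's mass range.  ``N_observable`` is derived here
by cutting the protein sequence at the canonical trypsin sites (C-terminal to
K or R, suppressed when the next residue is proline) and keeping peptides
whose monoisotopic mass falls inside a configurable window.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass
from pyteomics import parser as _pparser

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: trypsin: cleave after K or R unless the next residue is P
TRYPSIN_RULE = r"[KR](?=[^P])"

#: monoisotopic mass added per cysteine by carbamidomethylation
CARBAMIDOMETHYL_MASS = 57.021464

# defaults for the observable-peptide window (monoisotopic Da / residues)
DEFAULT_MIN_MASS = 500.0
DEFAULT_MAX_MASS = 3000.0
DEFAULT_MIN_LENGTH = 6


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with its monoisotopic mass in Da."""

    sequence: str
    monoisotopic_mass: float


@dataclass(frozen=True)
class EmpaiScore:
    protein_id: str
    n_observed: int
    n_observable: int
    pai: float
    empai: float


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - STANDARD_AA
    if not sequence:
        raise ValueError("empty protein sequence")
    if bad:
        raise ValueError(f"non-standard amino acids in sequence: {sorted(bad)}")


def peptide_mass(sequence: str, carbamidomethyl: bool = False) -> float:
    """Monoisotopic mass (neutral peptide, Da) of an amino-acid sequence."""
    m = _pmass.fast_mass(sequence)
    if carbamidomethyl:
        m += CARBAMIDOMETHYL_MASS * sequence.count("C")
    return m


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 0,
    carbamidomethyl: bool = False,
) -> list[Peptide]:
    """Cut a protein at trypsin sites and return fragments in sequence order.

    With ``missed_cleavages = 0`` the returned peptides partition the input;
    with ``m > 0`` every concatenation of up to ``m + 1`` adjacent fully
    cleaved fragments is additionally returned.
    """
    _validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    frags = sorted(
        _pparser.icleave(sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages),
        key=lambda t: (t[0], len(t[1])),
    )
    return [Peptide(pep, peptide_mass(pep, carbamidomethyl)) for _, pep in frags]


def count_observable(
    peptides: list[Peptide],
    min_mass: float = DEFAULT_MIN_MASS,
    max_mass: float = DEFAULT_MAX_MASS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> int:
    """Number of distinct peptide sequences inside the mass/length window."""
    if not min_mass < max_mass:
        raise ValueError("min_mass must be < max_mass")
    kept = {
        p.sequence
        for p in peptides
        if min_mass <= p.monoisotopic_mass <= max_mass and len(p.sequence) >= min_length
    }
    return len(kept)


def n_observable(
    sequence: str,
    min_mass: float = DEFAULT_MIN_MASS,
    max_mass: float = DEFAULT_MAX_MASS,
    min_length: int = DEFAULT_MIN_LENGTH,
    missed_cleavages: int = 0,
    carbamidomethyl: bool = False,
) -> int:
    """Convenience composition: digest then count observable peptides."""
    peps = digest_tryptic(sequence, missed_cleavages, carbamidomethyl)
    return count_observable(peps, min_mass, max_mass, min_length)


def compute_empai(n_observed: int, n_observable: int, protein_id: str = "") -> EmpaiScore:
    """emPAI = 10**(N_observed/N_observable) − 1.

    Raises ``ValueError`` for ``n_observable < 1`` (an unscorable protein is
    an error, not a zero score).
    """
    if n_observable < 1:
        raise ValueError(f"protein {protein_id!r} has no observable peptides; emPAI undefined")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    pai = n_observed / n_observable
    return EmpaiScore(protein_id, n_observed, n_observable, pai, 10.0**pai - 1.0)


def empai_value(n_observed: int, n_observable: int) -> float:
    """Bare emPAI number, for callers that do not need the full record."""
    return compute_empai(n_observed, n_observable).empai


def digest_table(records: dict[str, str], **window) -> "pandas.DataFrame":  # noqa: F821
    """Per-protein digestion summary (id, length, n_peptides, n_observable)."""
    import pandas as pd

    rows = []
    for pid, seq in records.items():
        peps = digest_tryptic(seq, window.get("missed_cleavages", 0),
                              window.get("carbamidomethyl", False))
        rows.append({
            "protein_id": pid,
            "length": len(seq),
            "n_peptides": len(peps),
            "n_observable": count_observable(
                peps,
                window.get("min_mass", DEFAULT_MIN_MASS),
                window.get("max_mass", DEFAULT_MAX_MASS),
                window.get("min_length", DEFAULT_MIN_LENGTH),
            ),
        })
    return pd.DataFrame(rows)
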