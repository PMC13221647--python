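"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the study designs this package analyses, so every
downstream stage can be exercised end to end without external data:

* TAP-MS pulldowns — a ground-truth architecture of two chromatin-remodeling
  complexes that share a subunit core, purified with tagged baits against
  untagged controls.  True co-complex members are detected per replicate
  with probability ``p_detect_member``; a fixed background pool contaminates
  tagged and control runs alike with probability ``p_contaminant``.  Distinct
  peptide counts for a detected protein are Binomial(N_observable, q),
  clipped to >= 1, which keeps the resulting emPAI inside (0, 9].
* an ordered genome — genes laid out along chromosomes with planted
  co-regulated clusters (|log2FC| >= effect size, Q < 0.05, optionally with
  one interior gap) against background noise truncated inside (-1, 1) so no
  spurious cluster can pass the calling rule, plus a Bernoulli-planted
  fraction of CCAAT-bearing promoters (motif position uniform in the window,
  orientation by fair coin); all other promoters are scrubbed motif-free on
  both strands.
* ChIP-qPCR Ct tables — IP Cts derived from a planted enrichment fraction
  and the input-dilution identity, plus Gaussian cycle noise.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import promoters as _prom

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str


@dataclass(frozen=True)
class ComplexTruth:
    """Ground-truth complex architecture for the TAP simulation."""

    complexes: Mapping[str, frozenset[str]]

    @property
    def shared(self) -> frozenset[str]:
        """Subunits belonging to more than one complex."""
        counts: dict[str, int] = {}
        for members in self.complexes.values():
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        return frozenset(m for m, c in counts.items() if c >= 2)

    @property
    def all_members(self) -> frozenset[str]:
        return frozenset().union(*self.complexes.values())

    def complexes_of(self, protein: str) -> set[str]:
        return {name for name, members in self.complexes.items() if protein in members}

    def true_label(self, protein: str) -> str:
        cx = self.complexes_of(protein)
        if len(cx) >= 2:
            return "shared"
        if len(cx) == 1:
            return f"specific:{next(iter(cx))}"
        return "unassigned"

    def co_complex_members(self, bait: str) -> frozenset[str]:
        cx = self.complexes_of(bait)
        if not cx:
            raise ValueError(f"bait {bait!r} is not a member of any complex")
        return frozenset().union(*(self.complexes[c] for c in cx))


@dataclass(frozen=True)
class PeptideObsModel:
    """Distinct-peptide counts given detection: Binomial(n_observable, q), >= 1."""

    q: float = 0.3
    n_observable: int | Mapping[str, int] = 30

    def n_for(self, protein: str) -> int:
        if isinstance(self.n_observable, int):
            return self.n_observable
        return int(self.n_observable[protein])


@dataclass(frozen=True)
class TapSimParams:
    p_detect_member: float = 0.95
    p_contaminant: float = 0.05
    n_replicates: int = 3
    peptide_obs_model: PeptideObsModel = field(default_factory=PeptideObsModel)
    background_proteins: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("p_detect_member", "p_contaminant"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random protein sequences over the 20 standard amino acids."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValueError("length range must satisfy 10 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        records.append(ProteinRecord(f"P{i + 1:05d}", seq))
    return records


def simulate_tap_runs(
    truth: ComplexTruth,
    params: TapSimParams,
    baits: Sequence[str],
    include_controls: bool = True,
) -> pd.DataFrame:
    """Long observation table for tagged runs (and untagged controls).

    Columns: run, bait, replicate, is_control, protein, peptides_observed.
    Tagged runs always contain the bait; true co-complex members are
    detected independently per replicate; background contaminants appear in
    tagged and control runs alike.  Control runs never contain complex
    members.
    """
    rng = np.random.default_rng(params.seed)
    model = params.peptide_obs_model
    rows: list[dict] = []

    def peptide_count(protein: str) -> int:
        n = model.n_for(protein)
        return max(1, int(rng.binomial(n, model.q)))

    for bait in baits:
        members = sorted(truth.co_complex_members(bait))  # validates the bait
        for rep in range(1, params.n_replicates + 1):
            detected = {bait}
            for m in members:
                if m != bait and rng.random() < params.p_detect_member:
                    detected.add(m)
            for c in params.background_proteins:
                if rng.random() < params.p_contaminant:
                    detected.add(c)
            for protein in sorted(detected):
                rows.append({
                    "run": f"{bait}-TAP-{rep}", "bait": bait, "replicate": rep,
                    "is_control": False, "protein": protein,
                    "peptides_observed": peptide_count(protein),
                })
    if include_controls:
        for rep in range(1, params.n_replicates + 1):
            for c in params.background_proteins:
                if rng.random() < params.p_contaminant:
                    rows.append({
                        "run": f"control-{rep}", "bait": "control", "replicate": rep,
                        "is_control": True, "protein": c,
                        "peptides_observed": peptide_count(c),
                    })
    return pd.DataFrame(
        rows, columns=["run", "bait", "replicate", "is_control", "protein",
                       "peptides_observed"],
    )


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: int        # 0-based chromosome index
    start: int             # 0-based ordinal of the first member on the chromosome
    length: int
    gap: int | None = None  # offset of the failing member within the cluster
    direction: str = "up"   # "up" | "down" | "mixed"
    effect_size: float = 1.0

    def __post_init__(self):
        if self.length < 6:
            raise ValueError("planted clusters need >= 6 genes")
        if self.effect_size < 1.0:
            raise ValueError("effect size must be >= 1 (the calling threshold)")
        if self.gap is not None:
            if self.length < 8:
                raise ValueError("a gapped cluster needs >= 8 genes")
            if not 0 < self.gap < self.length - 1:
                raise ValueError("the gap must be interior")


@dataclass(frozen=True)
class GenomeSimParams:
    n_genes: int = 1000
    n_chromosomes: int = 4
    planted_clusters: tuple[PlantedCluster, ...] = ()
    ccaat_fraction: float = 0.34
    promoter_len: int = 200
    gene_len: int = 300
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if not 0.0 <= self.ccaat_fraction <= 1.0:
            raise ValueError("ccaat_fraction must be in [0, 1]")
        spans: dict[int, list[tuple[int, int]]] = {}
        for cl in self.planted_clusters:
            spans.setdefault(cl.chromosome, []).append((cl.start, cl.start + cl.length))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"planted clusters overlap on chromosome {chrom}")


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: pd.DataFrame        # gene_id, chromosome, ordinal, start, end, strand
    expression: pd.DataFrame   # gene_id, chromosome, ordinal, strand, log2fc, qvalue, deg_call
    truth: dict


def _chromosome_gene_counts(n_genes: int, n_chromosomes: int) -> list[int]:
    base, extra = divmod(n_genes, n_chromosomes)
    return [base + (1 if i < extra else 0) for i in range(n_chromosomes)]


_MOTIF_RE = re.compile("CCAAT|ATTGG")


def _scrub_motifs(window: bytearray) -> None:
    """Destroy every CCAAT/ATTGG occurrence in place (both strands covered)."""
    s = window.decode()
    while True:
        m = _MOTIF_RE.search(s)
        if m is None:
            break
        # one substitution at the motif's 4th base breaks it without
        # guaranteeing anything else, so re-scan until clean
        repl = b"G" if s[m.start()] == "C" else b"C"
        window[m.start() + 3:m.start() + 4] = repl
        s = window.decode()


def generate_genome_with_clusters(params: GenomeSimParams) -> SimulatedGenome:
    """Genome FASTA + gene models + expression table + truth for one seed."""
    rng = np.random.default_rng(params.seed)
    L = params.promoter_len
    spacer = L + 10
    slot = spacer + params.gene_len + spacer

    counts = _chromosome_gene_counts(params.n_genes, params.n_chromosomes)
    truth_clusters = []
    cluster_lfc: dict[tuple[int, int], float] = {}  # (chrom, ordinal) -> planted lfc
    cluster_gap: set[tuple[int, int]] = set()
    for cl in params.planted_clusters:
        if cl.chromosome >= params.n_chromosomes:
            raise ValueError("planted cluster on a nonexistent chromosome")
        if cl.start + cl.length > counts[cl.chromosome]:
            raise ValueError("planted cluster exceeds chromosome gene count")
        for off in range(cl.length):
            key = (cl.chromosome, cl.start + off)
            if cl.gap is not None and off == cl.gap:
                cluster_gap.add(key)
                continue
            mag = cl.effect_size + abs(rng.normal(0.0, 0.2))
            if cl.direction == "up":
                sign = 1.0
            elif cl.direction == "down":
                sign = -1.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
            cluster_lfc[key] = sign * mag

    genome: dict[str, str] = {}
    gene_rows, expr_rows, ccaat_genes = [], [], []
    for ci, n_on_chrom in enumerate(counts):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(BASES, size=slot * n_on_chrom).astype(np.uint8)
        chrom_seq = bytearray(seq.tobytes())
        for gi in range(n_on_chrom):
            gene_id = f"g{ci + 1:02d}_{gi + 1:05d}"
            offset = gi * slot
            start = offset + spacer + 1            # 1-based inclusive
            end = start + params.gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                w_lo, w_hi = start - L, start - 1   # 1-based
            else:
                w_lo, w_hi = end + 1, end + L
            window = chrom_seq[w_lo - 1:w_hi]
            _scrub_motifs(window)
            has_ccaat = rng.random() < params.ccaat_fraction
            if has_ccaat:
                pos = int(rng.integers(0, L - 4))
                motif = b"CCAAT" if rng.random() < 0.5 else b"ATTGG"
                window[pos:pos + 5] = motif
                ccaat_genes.append(gene_id)
            chrom_seq[w_lo - 1:w_hi] = window

            key = (ci, gi)
            if key in cluster_lfc:
                lfc = cluster_lfc[key]
                q = float(rng.uniform(0.0, 0.049))
            else:
                # background (and gap) genes: truncated Gaussian strictly inside
                # the calling threshold, so they can never pass the rule
                while True:
                    lfc = float(rng.normal(0.0, params.noise_sd))
                    if abs(lfc) < 1.0:
                        break
                q = float(rng.uniform(0.0, 1.0))
            gene_rows.append({
                "gene_id": gene_id, "chromosome": chrom, "ordinal": gi,
                "start": start, "end": end, "strand": strand,
            })
            expr_rows.append({
                "gene_id": gene_id, "chromosome": chrom, "ordinal": gi,
                "strand": strand, "log2fc": float(lfc), "qvalue": q,
            })
        genome[chrom] = chrom_seq.decode()

    genes = pd.DataFrame(gene_rows)
    expression = pd.DataFrame(expr_rows)
    from .clusters import classify_deg
    expression["deg_call"] = [
        classify_deg(r.log2fc, r.qvalue) for r in expression.itertuples()
    ]
    for cl in params.planted_clusters:
        chrom = f"chr{cl.chromosome + 1}"
        ids = genes.loc[(genes["chromosome"] == chrom)
                        & (genes["ordinal"] >= cl.start)
                        & (genes["ordinal"] < cl.start + cl.length), "gene_id"]
        truth_clusters.append({
            "chromosome": chrom, "start_ordinal": cl.start, "size": cl.length,
            "gap_ordinal": None if cl.gap is None else cl.start + cl.gap,
            "gene_ids": list(ids),
        })
    truth = {"clusters": truth_clusters, "ccaat_genes": ccaat_genes,
             "ccaat_fraction": params.ccaat_fraction}
    return SimulatedGenome(genome, genes, expression, truth)


def simulate_ct_table(
    true_enrichment: Mapping[str, float],
    input_fraction: float = 0.1,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    base_input_ct: float = 25.0,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Paired IP/input Ct rows from planted percent-of-input enrichments.

    The IP Ct follows the percent-of-input identity
    ``Ct_IP = Ct_Input + log2(input_fraction) - log2(enrichment)`` plus
    Gaussian cycle noise, so a noise-free table inverts exactly to the
    planted enrichment.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for locus, enrichment in true_enrichment.items():
        if enrichment <= 0:
            raise ValueError(f"enrichment for {locus!r} must be positive")
        for rep in range(1, n_replicates + 1):
            ct_input = base_input_ct
            ct_ip = (ct_input + np.log2(input_fraction) - np.log2(enrichment)
                     + rng.normal(0.0, noise_sd))
            rows.append({"sample_id": sample_id, "locus": locus, "role": "input",
                         "replicate": rep, "ct": float(ct_input)})
            rows.append({"sample_id": sample_id, "locus": locus, "role": "IP",
                         "replicate": rep, "ct": float(ct_ip)})
    return pd.DataFrame(rows)


def default_two_complex_truth(
    n_shared: int = 6, n_specific: int = 6,
    names: tuple[str, str] = ("SWI/SNF", "RSC"),
) -> ComplexTruth:
    """Two complexes with a shared core, mirroring a SWI/SNF–RSC architecture."""
    shared = [f"core{i + 1}" for i in range(n_shared)]
    a_only = [f"swi{i + 1}" for i in range(n_specific)]
    b_only = [f"rsc{i + 1}" for i in range(n_specific)]
    return ComplexTruth({
        names[0]: frozenset(shared + a_only),
        names[1]: frozenset(shared + b_only),
    })


def _prom_roundtrip_check(sim: SimulatedGenome, length: int) -> float:
    """Fraction of generated promoters carrying a CCAAT box (either strand)."""
    windows = _prom.extract_promoters(sim.genes, sim.genome, length)
    hits = [_prom.scan_ccaat(w) for w in windows]
    return sum(h.has_motif for h in hits) / len(hits)
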