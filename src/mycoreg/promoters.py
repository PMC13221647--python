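"""Promoter windows and CCAAT-box scanning.

The CCAAT box is the binding element of the heterotrimeric NF-Y
transcription factor.  The analysis extracts a fixed-length window upstream
of each gene's annotated start (strand aware, default 200 bp), scans it for
CCAAT on both strands — a reverse-strand CCAAT reads ATTGG on the forward
string — and compares the fraction of motif-bearing promoters in a gene set
against the genome-wide background with an exact binomial test.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

MOTIF_FWD = "CCAAT"
MOTIF_REV = "ATTGG"  # reverse complement of CCAAT
DEFAULT_PROMOTER_LEN = 200

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chromosome: str
    start: int   # 1-based inclusive, on the forward genome strand
    end: int     # 1-based inclusive; end < start encodes an empty window
    strand: str
    sequence: str  # promoter sense (reverse-complemented for minus-strand genes)

    def to_bed(self) -> tuple[str, int, int, str, str]:
        """0-based half-open BED record."""
        return (self.chromosome, self.start - 1, self.end, self.gene_id, self.strand)


@dataclass(frozen=True)
class MotifHitSet:
    gene_id: str
    hits: tuple[tuple[int, str], ...]  # (0-based offset in window, "+"/"-")

    @property
    def has_motif(self) -> bool:
        return bool(self.hits)


def extract_promoters(
    genes: "pandas.DataFrame",  # noqa: F821
    genome: Mapping[str, str],
    length: int = DEFAULT_PROMOTER_LEN,
) -> list[PromoterWindow]:
    """Upstream windows for every gene in a gene-model table.

    ``genes`` needs columns gene_id, chromosome, start, end, strand with
    1-based inclusive coordinates.  For a plus-strand gene the window is the
    ``length`` bases ending immediately before ``start``; for a minus-strand
    gene, the ``length`` bases beginning immediately after ``end``,
    reverse-complemented.  Windows are clipped (with a warning) at
    chromosome edges; a fully clipped window has an empty sequence.
    """
    windows = []
    for _, g in genes.iterrows():
        chrom = str(g["chromosome"])
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        chrom_seq = genome[chrom]
        clen = len(chrom_seq)
        if g["strand"] == "+":
            w_end = int(g["start"]) - 1
            w_start = max(1, w_end - length + 1)
        else:
            w_start = int(g["end"]) + 1
            w_end = min(clen, w_start + length - 1)
        if w_end - w_start + 1 < length:
            warnings.warn(f"promoter of {g['gene_id']} clipped at chromosome edge")
        seq = chrom_seq[w_start - 1:w_end] if w_end >= w_start else ""
        if g["strand"] == "-":
            seq = reverse_complement(seq)
        windows.append(PromoterWindow(
            str(g["gene_id"]), chrom, w_start, max(w_start - 1, w_end),
            str(g["strand"]), seq.upper(),
        ))
    return windows


def scan_ccaat(window: PromoterWindow | str, both_strands: bool = True,
               gene_id: str = "") -> MotifHitSet:
    """All CCAAT occurrences in a promoter window, overlapping ones included.

    Forward hits match CCAAT in the window string; with ``both_strands``
    (default on) ATTGG occurrences are reported as reverse-orientation hits.
    N never matches.
    """
    if isinstance(window, PromoterWindow):
        seq, gene_id = window.sequence, window.gene_id
    else:
        seq = window.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("promoter sequence must be over ACGTN")
    hits = [(m.start(), "+") for m in re.finditer(f"(?={MOTIF_FWD})", seq)]
    if both_strands:
        hits += [(m.start(), "-") for m in re.finditer(f"(?={MOTIF_REV})", seq)]
    return MotifHitSet(gene_id, tuple(sorted(hits)))


def proportion_with_motif(
    hitsets: Iterable[MotifHitSet],
    gene_subset: set[str] | None = None,
) -> tuple[int, int, float]:
    """(count with motif, total, percent) over all or a subset of genes.

    The percent is reported to one decimal, matching how such genome-wide
    proportions are conventionally printed.
    """
    sets = list(hitsets)
    if gene_subset is not None:
        known = {h.gene_id for h in sets}
        missing = gene_subset - known
        if missing:
            raise ValueError(f"subset genes never scanned: {sorted(missing)[:5]}...")
        sets = [h for h in sets if h.gene_id in gene_subset]
    if not sets:
        raise ValueError("empty gene set")
    with_motif = sum(1 for h in sets if h.has_motif)
    total = len(sets)
    return with_motif, total, round(100.0 * with_motif / total, 1)


def exact_binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by doubling the smaller tail (cap 1).

    Degenerate backgrounds (p0 = 0 with k = 0, or p0 = 1 with k = n) give 1.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("background proportion must be in [0, 1]")
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def compare_to_background(
    subset_count: int,
    subset_n: int,
    background_proportion: float,
) -> dict:
    """Enrichment report of a gene subset's motif proportion vs background."""
    if subset_n < 1:
        raise ValueError("subset must contain at least one gene")
    prop = subset_count / subset_n
    return {
        "subset_count": subset_count,
        "subset_n": subset_n,
        "subset_proportion": prop,
        "background_proportion": background_proportion,
        "difference": prop - background_proportion,
        "p_value": exact_binomial_two_sided(subset_count, subset_n, background_proportion),
    }
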