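"""Differential-expression calls and physically linked co-regulated clusters.

A co-regulated cluster is a maximal run of neighbouring genes (in genomic
order, strand ignored) whose expression responds to a perturbation:

* rule (a): at least 6 contiguous genes all with |log2FC| >= 1, or
* rule (b): at least 8 contiguous genes containing exactly one interior
  gene below threshold (a single "gap").

Maximality means no reported cluster can be extended by an adjacent gene
while still satisfying (a) or (b).  Such clusters frequently coincide with
secondary-metabolite biosynthetic gene clusters (BGCs), so each called
cluster is annotated with its overlap class against a BGC interval table.

Note that two maximal one-gap windows may legitimately overlap (e.g. the
pattern 6 passes, gap, 6 passes, gap, 6 passes yields two 13-gene windows
sharing the middle run); both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

MIN_RUN = 6          # rule (a): contiguous passing genes
MIN_GAPPED_RUN = 8   # rule (b): total genes when one interior gap is allowed

DEG_LFC_THRESHOLD = 1.0
DEG_Q_THRESHOLD = 0.05


@dataclass(frozen=True)
class CoRegulatedCluster:
    chromosome: str
    first_gene: str
    genes: tuple[str, ...]
    start_ordinal: int          # ordinal of the first member within the chromosome
    gap_ordinals: tuple[int, ...]  # ordinals of non-passing interior members (0 or 1)
    direction: str              # "up" | "down" | "mixed"
    bgc_overlap: str = "none"   # "complete" | "partial" | "none"
    bgc_id: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def compute_log2fc(
    mutant_fpkm: Sequence[float],
    wt_fpkm: Sequence[float],
    pseudocount: float = 0.0,
) -> float:
    """log2((mean mutant FPKM + c) / (mean WT FPKM + c))."""
    if len(mutant_fpkm) == 0 or len(wt_fpkm) == 0:
        raise ValueError("need at least one replicate per condition")
    mut = float(np.mean(mutant_fpkm)) + pseudocount
    wt = float(np.mean(wt_fpkm)) + pseudocount
    if wt <= 0:
        raise ValueError("WT mean + pseudocount must be positive for a defined ratio")
    if mut <= 0:
        raise ValueError("mutant mean + pseudocount must be positive for a defined ratio")
    return float(np.log2(mut / wt))


def classify_deg(log2fc: float, qvalue: float) -> str:
    """"up" / "down" / "ns" at |log2FC| >= 1 (inclusive) and Q < 0.05 (strict)."""
    if not 0.0 <= qvalue <= 1.0:
        raise ValueError("qvalue must be in [0, 1]")
    if qvalue < DEG_Q_THRESHOLD:
        if log2fc >= DEG_LFC_THRESHOLD:
            return "up"
        if log2fc <= -DEG_LFC_THRESHOLD:
            return "down"
    return "ns"


def _pass_runs(passes: Sequence[bool]) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True."""
    runs = []
    i, n = 0, len(passes)
    while i < n:
        if passes[i]:
            j = i
            while j < n and passes[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def call_cluster_spans(passes: Sequence[bool]) -> list[tuple[int, int, int | None]]:
    """Maximal cluster windows over a pass/fail vector.

    Returns (start, stop, gap_index) with stop exclusive and gap_index the
    position of the single non-passing member of a rule-(b) window (None for
    gap-free rule-(a) windows).  Works on the run-length encoding: a one-gap
    window is fully determined by two pass runs separated by exactly one
    failing gene, and a pass run is reported on its own only when it is at
    least 6 long and not absorbed by such a window.
    """
    runs = _pass_runs(passes)
    spans: list[tuple[int, int, int | None]] = []
    in_gapped = [False] * len(runs)
    for k in range(len(runs) - 1):
        s1, l1 = runs[k]
        s2, l2 = runs[k + 1]
        if s2 - (s1 + l1) == 1 and l1 + 1 + l2 >= MIN_GAPPED_RUN:
            spans.append((s1, s2 + l2, s1 + l1))
            in_gapped[k] = in_gapped[k + 1] = True
    for k, (s, l) in enumerate(runs):
        if l >= MIN_RUN and not in_gapped[k]:
            spans.append((s, s + l, None))
    spans.sort()
    return spans


def default_pass_predicate(require_q: bool = False) -> Callable[[pd.Series], bool]:
    """Cluster membership test: |log2FC| >= 1, optionally also Q < 0.05."""
    def pred(row: pd.Series) -> bool:
        ok = abs(float(row["log2fc"])) >= DEG_LFC_THRESHOLD
        if require_q:
            ok = ok and float(row["qvalue"]) < DEG_Q_THRESHOLD
        return ok
    return pred


def call_clusters(
    records: pd.DataFrame,
    pass_predicate: Callable[[pd.Series], bool] | None = None,
    require_q: bool = False,
) -> list[CoRegulatedCluster]:
    """Call all maximal co-regulated clusters on an expression table.

    ``records`` needs columns gene_id, chromosome, ordinal, log2fc (qvalue
    only if the predicate uses it); rows must be sorted by ordinal within
    each chromosome and ordinals must be consecutive.
    """
    pred = pass_predicate or default_pass_predicate(require_q)
    clusters: list[CoRegulatedCluster] = []
    for chrom, grp in records.groupby("chromosome", sort=True):
        ords = grp["ordinal"].to_numpy()
        if not (np.all(np.diff(ords) == 1)):
            raise ValueError(f"gene ordinals on {chrom} are not sorted/consecutive")
        passes = [bool(pred(row)) for _, row in grp.iterrows()]
        genes = grp["gene_id"].tolist()
        lfc = grp["log2fc"].to_numpy(dtype=float)
        base = int(ords[0])
        for start, stop, gap in call_cluster_spans(passes):
            member_lfc = [lfc[i] for i in range(start, stop) if i != gap]
            if all(v >= 0 for v in member_lfc):
                direction = "up"
            elif all(v <= 0 for v in member_lfc):
                direction = "down"
            else:
                direction = "mixed"
            clusters.append(CoRegulatedCluster(
                chromosome=str(chrom),
                first_gene=genes[start],
                genes=tuple(genes[start:stop]),
                start_ordinal=base + start,
                gap_ordinals=() if gap is None else (base + gap,),
                direction=direction,
            ))
    return clusters


def annotate_bgc_overlap(
    clusters: Iterable[CoRegulatedCluster],
    bgc_table: pd.DataFrame,
) -> list[CoRegulatedCluster]:
    """Set each cluster's overlap class against BGC gene-ordinal intervals.

    ``bgc_table`` columns: bgc_id, chromosome, start_ordinal, end_ordinal
    (inclusive, same gene ordering as the expression table).  "complete"
    means the cluster's gene span and the BGC span are nested either way;
    "partial" any other nonempty intersection.  When several BGCs intersect
    a cluster the strongest class (complete over partial, then larger
    intersection) wins.
    """
    out = []
    for cl in clusters:
        span = set(range(cl.start_ordinal, cl.start_ordinal + cl.size))
        best = ("none", None, 0)
        for _, b in bgc_table.iterrows():
            if str(b["chromosome"]) != cl.chromosome:
                continue
            bspan = set(range(int(b["start_ordinal"]), int(b["end_ordinal"]) + 1))
            inter = span & bspan
            if not inter:
                continue
            klass = "complete" if (span <= bspan or bspan <= span) else "partial"
            key = (2 if klass == "complete" else 1, len(inter))
            if key > (2 if best[0] == "complete" else (1 if best[0] == "partial" else 0), best[2]):
                best = (klass, str(b["bgc_id"]), len(inter))
        out.append(CoRegulatedCluster(
            cl.chromosome, cl.first_gene, cl.genes, cl.start_ordinal,
            cl.gap_ordinals, cl.direction, best[0], best[1],
        ))
    return out


def clusters_to_frame(clusters: Iterable[CoRegulatedCluster]) -> pd.DataFrame:
    """Flat report table; clusters named by their first locus tag."""
    rows = [{
        "cluster": f"C-{c.first_gene}",
        "chromosome": c.chromosome,
        "first_gene": c.first_gene,
        "size": c.size,
        "n_gaps": len(c.gap_ordinals),
        "direction": c.direction,
        "bgc_overlap": c.bgc_overlap,
        "bgc_id": c.bgc_id or "",
    } for c in clusters]
    return pd.DataFrame(rows)
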