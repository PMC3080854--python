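"""Sequence-context comparison of methylation-variable vs invariant promoters.

Promoter windows run from 1000 bp upstream to 500 bp downstream of the TSS
(strand-aware, 0-based half-open).  The promoters nearest the most-variable
probes are compared against those nearest the least-variable probes on GC
content, repeat-element frequency per class (chi-square) and the distribution
of TSS-to-element-midpoint distances (unpaired t-test).  Bisulphite clone
matrices (clones x CpGs, 0/1) are summarized as overall percent methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

UPSTREAM = 1000
DOWNSTREAM = 500

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Simple_repeat", "Low_complexity",
                  "Microsatellite", "DNA")


@dataclass
class PromoterWindow:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    tss: int
    sequence: str | None = None
    gc: float | None = None
    clipped: bool = False


def window_for_tss(tss: int, strand: str, upstream: int = UPSTREAM,
                   downstream: int = DOWNSTREAM,
                   contig_length: int | None = None):
    """Promoter interval for a TSS, 0-based half-open, strand-aware.

    Plus strand: [tss - upstream, tss + downstream); minus strand:
    [tss - downstream, tss + upstream).  Windows clipped at contig edges are
    flagged.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if contig_length is not None and end > contig_length:
        end, clipped = contig_length, True
    return start, end, clipped


def read_tss_bed(path) -> pd.DataFrame:
    """BED6 of TSSs: chrom, start, end, gene id, score, strand (mandatory)."""
    tss = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id", "score",
                             "strand"])
    if tss["strand"].isna().any() or not set(tss["strand"]) <= {"+", "-"}:
        raise ValueError("TSS BED requires a '+'/'-' strand for every record")
    return tss


def tss_position(row) -> int:
    """TSS coordinate of a (usually single-base) BED record: the interval
    start on the plus strand, the last base on the minus strand."""
    return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes excluded from the
    denominator.  Case-insensitive; undefined (NaN) for all-N input."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def promoter_windows(tss: pd.DataFrame, ranking: pd.Series,
                     probe_positions: pd.DataFrame, n_top: int = 100,
                     n_bottom: int = 1000, fasta=None):
    """Promoter windows for the most- and least-variable probes.

    ``ranking`` is a per-probe variability score (e.g. control-group SD);
    each of the ``n_top`` highest-ranked and ``n_bottom`` lowest-ranked
    probes is assigned its nearest TSS (by distance from probe midpoint,
    ties broken by smallest gene id) and that gene's promoter window is
    emitted, deduplicated.  ``probe_positions`` needs columns chrom/start/end
    indexed by probe id; ``fasta`` is an optional pyfaidx.Fasta for sequence
    and GC extraction.

    Returns ``(variable_windows, invariant_windows)`` as lists of
    :class:`PromoterWindow`.
    """
    ranking = ranking.dropna().sort_values()
    top = list(ranking.index[-n_top:]) if n_top else []
    bottom = list(ranking.index[:n_bottom]) if n_bottom else []

    tss = tss.copy()
    tss["tss"] = tss.apply(tss_position, axis=1)

    def nearest_gene(probe_id):
        row = probe_positions.loc[probe_id]
        mid = (int(row["start"]) + int(row["end"])) // 2
        cand = tss[tss["chrom"] == row["chrom"]]
        if cand.empty:
            return None
        dist = (cand["tss"] - mid).abs()
        best = cand.loc[dist == dist.min()].sort_values("gene_id")
        return best.iloc[0]

    def build(probes):
        seen, out = set(), []
        for p in probes:
            g = nearest_gene(p)
            if g is None:
                logger.warning("probe %s: no TSS on its chromosome", p)
                continue
            if g["gene_id"] in seen:
                logger.debug("gene %s already selected; deduplicated", g["gene_id"])
                continue
            seen.add(g["gene_id"])
            contig_len = len(fasta[g["chrom"]]) if fasta is not None else None
            start, end, clipped = window_for_tss(int(g["tss"]), g["strand"],
                                                 contig_length=contig_len)
            seq = gc = None
            if fasta is not None:
                seq = str(fasta[g["chrom"]][start:end])
                if g["strand"] == "-":
                    seq = _revcomp(seq)
                gc = gc_content(seq)
            out.append(PromoterWindow(gene_id=g["gene_id"], chrom=g["chrom"],
                                      strand=g["strand"], start=start, end=end,
                                      tss=int(g["tss"]), sequence=seq, gc=gc,
                                      clipped=clipped))
        return out

    return build(top), build(bottom)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_repeats_bed(path) -> pd.DataFrame:
    """BED with a repeat-class name column: chrom, start, end, class."""
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                       names=["chrom", "start", "end", "repeat_class"])


def _element_distances(windows, repeats: pd.DataFrame, repeat_class: str):
    """Signed TSS-to-midpoint distances of class elements inside windows
    (downstream of the TSS positive, strand-aware), plus the per-promoter
    presence indicator."""
    trees: dict[str, IntervalTree] = {}
    sub = repeats[repeats["repeat_class"] == repeat_class]
    for chrom, rows in sub.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end)) for r in rows.itertuples()
            if r.end > r.start)
    distances, present = [], []
    for w in windows:
        tree = trees.get(w.chrom)
        hits = sorted(tree.overlap(w.start, w.end)) if tree else []
        present.append(bool(hits))
        for iv in hits:
            mid = (iv.begin + iv.end) / 2
            d = mid - w.tss if w.strand == "+" else w.tss - mid
            distances.append(d)
    return np.array(distances, dtype=float), np.array(present, dtype=bool)


def compare_promoter_features(variable, invariant, repeats: pd.DataFrame | None,
                              repeat_classes=REPEAT_CLASSES) -> pd.DataFrame:
    """Feature comparison between variable and invariant promoter sets.

    Per repeat class: a chi-square test on the 2x2 table of promoters
    containing >= 1 element vs not, and an unpaired (Welch) t-test comparing
    the TSS-to-element-midpoint distance distributions.  GC content is
    compared by a Welch t-test when windows carry sequences/GC values.
    Classes absent from both sets are skipped with a log message.
    """
    rows = []
    gc_var = np.array([w.gc for w in variable if w.gc is not None], dtype=float)
    gc_inv = np.array([w.gc for w in invariant if w.gc is not None], dtype=float)
    if gc_var.size >= 2 and gc_inv.size >= 2:
        stat, p = _welch_or_zero(gc_var, gc_inv)
        rows.append({"feature": "GC_content", "test": "welch_t",
                     "statistic": stat, "pvalue": p,
                     "mean_variable": gc_var.mean(), "mean_invariant": gc_inv.mean(),
                     "n_variable": gc_var.size, "n_invariant": gc_inv.size})
    if repeats is not None:
        for cls in repeat_classes:
            d_var, pres_var = _element_distances(variable, repeats, cls)
            d_inv, pres_inv = _element_distances(invariant, repeats, cls)
            if d_var.size == 0 and d_inv.size == 0:
                logger.info("repeat class %s absent from both sets; skipped", cls)
                continue
            table = np.array([[pres_var.sum(), (~pres_var).sum()],
                              [pres_inv.sum(), (~pres_inv).sum()]])
            if table.sum(axis=1).min() == 0:
                chi2, p_freq = np.nan, np.nan  # one set empty
            elif table.sum(axis=0).min() == 0:
                # both sets at the same extreme (all or none contain the
                # element): no frequency difference by construction
                chi2, p_freq = 0.0, 1.0
            else:
                chi2, p_freq = _chi2_2x2(table)
            rows.append({"feature": f"{cls}_frequency", "test": "chi2",
                         "statistic": chi2, "pvalue": p_freq,
                         "mean_variable": pres_var.mean() if pres_var.size else np.nan,
                         "mean_invariant": pres_inv.mean() if pres_inv.size else np.nan,
                         "n_variable": int(pres_var.sum()),
                         "n_invariant": int(pres_inv.sum())})
            if d_var.size >= 2 and d_inv.size >= 2:
                t, p_dist = _welch_or_zero(d_var, d_inv)
                rows.append({"feature": f"{cls}_tss_distance", "test": "welch_t",
                             "statistic": t, "pvalue": p_dist,
                             "mean_variable": d_var.mean(),
                             "mean_invariant": d_inv.mean(),
                             "n_variable": d_var.size, "n_invariant": d_inv.size})
    return pd.DataFrame(rows)


def _welch_or_zero(a, b):
    """Welch t-test; identical degenerate samples give t = 0, p = 1."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _chi2_2x2(table):
    """Pearson chi-square without continuity correction; a table equal to
    its independence expectation gives statistic exactly 0."""
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# bisulphite clone maps
# ---------------------------------------------------------------------------

def read_clone_matrix(path) -> pd.DataFrame:
    """Tab-delimited clones x CpG-sites binary (0/1) methylation calls."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    vals = mat.to_numpy()
    if not np.isin(vals[np.isfinite(vals)], (0, 1)).all():
        raise ValueError("clone matrix entries must be 0 or 1")
    return mat


def percent_methylation(clones) -> float:
    """Overall percent methylation of a bisulphite clone map:
    100 * methylated calls / total calls (missing entries excluded)."""
    vals = np.asarray(clones, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty clone matrix")
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("clone matrix entries must be 0 or 1")
    return float(100.0 * vals.mean())
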