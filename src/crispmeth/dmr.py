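"""Windowed Fisher-exact differential-methylation calling.

The procedure: replicate call tables are pooled per group; sliding windows
that contain at least ``min_cpg`` covered CpG sites are tested with a
two-sided Fisher exact test on the pooled 2x2 read-count table
(methylated/unmethylated x group); windows with a two-fold change in the
pooled methylation level and p <= 0.05 are significant; overlapping or
adjacent significant windows with the same direction merge into DMRs, whose
statistics are recomputed over the merged span.  Genes whose promoter a DMR
overlaps are the promoter DMGs.

Pooled levels follow Rm = Nm_all / (Nm_all + Nnm_all): read counts are summed
over every replicate and site before dividing.  For the CG context the two
strands of a symmetric CpG are merged onto the forward-strand C before
windowing; CHG/CHH sites stay strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import AnnotationSet

FOLD_EPS = 1e-6

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_cpg", "meth_a", "total_a", "meth_b", "total_b",
    "level_a", "level_b", "fold_change", "p_value", "direction",
]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Conditions on both margins and sums the hypergeometric probabilities of
    all tables no more likely than the observed one (within 1e-12 relative
    tolerance, so exact ties on symmetric tables are included).  The
    all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(r1, k)
    support = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(k - support + 1)
        - gammaln(r2 - k + support + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    p_obs = w[a - lo]
    return float(min(1.0, w[w <= p_obs * (1.0 + 1e-12)].sum()))


def fold_change(level_a: float, level_b: float, eps: float = FOLD_EPS) -> float:
    """Ratio of the larger to the smaller level, floored by ``eps``."""
    hi, lo = max(level_a, level_b), min(level_a, level_b)
    return hi / max(lo, eps)


# ---------------------------------------------------------------------------
# pooling


def pool_replicates(tables: list[pd.DataFrame], context: str | None = None,
                    merge_cg_strands: bool = True) -> pd.DataFrame:
    """Sum meth/total over replicates per site.

    With ``merge_cg_strands`` the reverse-strand C of a symmetric CpG
    (forward-strand G at pos) is folded onto the forward C at pos - 1, so a
    CpG dinucleotide becomes one strand-merged unit.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    cat = pd.concat(tables, ignore_index=True)
    if context is not None:
        cat = cat[cat["context"] == context]
    cat = cat.copy()
    if merge_cg_strands:
        is_rev_cg = (cat["context"] == "CG") & (cat["strand"] == "-")
        cat.loc[is_rev_cg, "pos"] = cat.loc[is_rev_cg, "pos"] - 1
    pooled = (
        cat.groupby(["chrom", "pos", "context"], observed=True, sort=True)[
            ["meth", "total"]
        ]
        .sum()
        .reset_index()
    )
    return pooled


def _joint_sites(pooled_a: pd.DataFrame, pooled_b: pd.DataFrame,
                 context: str, min_total: int) -> pd.DataFrame:
    """Sites covered at >= min_total pooled reads in BOTH groups."""
    a = pooled_a[(pooled_a["context"] == context) & (pooled_a["total"] >= min_total)]
    b = pooled_b[(pooled_b["context"] == context) & (pooled_b["total"] >= min_total)]
    j = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    return j.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def pool_counts(
    pooled_a: pd.DataFrame,
    pooled_b: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str = "CG",
    min_total: int = 4,
) -> tuple[int, int, int, int, int]:
    """Pooled (meth_a, total_a, meth_b, total_b, n_cpg) over an interval.

    Counts sum over the context sites inside [start, end) that meet the
    per-site coverage floor in both pooled groups; ``n_cpg`` counts
    strand-merged CpG units for the CG context.
    """
    j = _joint_sites(pooled_a, pooled_b, context, min_total)
    j = j[(j["chrom"] == chrom) & (j["pos"] >= start) & (j["pos"] < end)]
    return (
        int(j["meth_a"].sum()), int(j["total_a"].sum()),
        int(j["meth_b"].sum()), int(j["total_b"].sum()),
        int(len(j)),
    )


# ---------------------------------------------------------------------------
# window scan


def scan_windows(
    tables_a: list[pd.DataFrame],
    tables_b: list[pd.DataFrame],
    context: str = "CG",
    width: int = 1000,
    step: int = 500,
    min_cpg: int = 5,
    min_total: int = 4,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Slide windows over the genome and Fisher-test pooled group counts.

    Windows with fewer than ``min_cpg`` covered CpG sites are dropped.
    Returns a window table (one row per retained window) with pooled counts,
    levels, fold change, two-sided Fisher p and direction.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        import warnings

        warnings.warn("step exceeds width: genome coverage has gaps")
    pa = pool_replicates(tables_a, context)
    pb = pool_replicates(tables_b, context)
    joint = _joint_sites(pa, pb, context, min_total)
    rows = []
    for chrom, sub in joint.groupby("chrom", observed=True, sort=True):
        pos = sub["pos"].to_numpy()
        ma = np.concatenate([[0], np.cumsum(sub["meth_a"].to_numpy())])
        ta = np.concatenate([[0], np.cumsum(sub["total_a"].to_numpy())])
        mb = np.concatenate([[0], np.cumsum(sub["meth_b"].to_numpy())])
        tb = np.concatenate([[0], np.cumsum(sub["total_b"].to_numpy())])
        if chrom_lengths and chrom in chrom_lengths:
            last = chrom_lengths[chrom]
        else:
            last = int(pos[-1]) + 1
        starts = np.arange(0, max(last - width, 0) + 1, step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, starts + width, side="left")
        n_cpg = i1 - i0
        keep = n_cpg >= min_cpg
        for s, a0, a1, nc in zip(starts[keep], i0[keep], i1[keep], n_cpg[keep]):
            meth_a, tot_a = int(ma[a1] - ma[a0]), int(ta[a1] - ta[a0])
            meth_b, tot_b = int(mb[a1] - mb[a0]), int(tb[a1] - tb[a0])
            la, lb = meth_a / tot_a, meth_b / tot_b
            rows.append(
                {
                    "chrom": chrom, "start": int(s), "end": int(s) + width,
                    "n_cpg": int(nc),
                    "meth_a": meth_a, "total_a": tot_a,
                    "meth_b": meth_b, "total_b": tot_b,
                    "level_a": la, "level_b": lb,
                    "fold_change": fold_change(la, lb),
                    "p_value": fisher_two_sided(
                        meth_a, tot_a - meth_a, meth_b, tot_b - meth_b
                    ),
                    "direction": "hyper_in_A" if la >= lb else "hypo_in_A",
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# DMR calling


DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpg", "meth_a", "total_a", "meth_b", "total_b",
    "level_a", "level_b", "fold_change", "p_value", "direction", "context",
    "n_windows", "q_value",
]


def call_dmrs(
    windows: pd.DataFrame,
    p_max: float = 0.05,
    min_fold: float = 2.0,
    min_cpg: int = 5,
    context: str = "CG",
    pooled_a: pd.DataFrame | None = None,
    pooled_b: pd.DataFrame | None = None,
    min_total: int = 4,
) -> pd.DataFrame:
    """Filter significant windows and merge them into DMRs.

    A window passes when n_cpg >= ``min_cpg``, fold change >= ``min_fold``
    and p <= ``p_max``.  Overlapping or book-ended passing windows with the
    same direction merge; merged statistics are recomputed over the merged
    span from the pooled site tables when given, otherwise from the union of
    constituent windows' disjoint contributions.  A Benjamini-Hochberg
    q value across all scanned windows is attached for reference.
    """
    if len(windows) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)
    from statsmodels.stats.multitest import multipletests

    windows = windows.reset_index(drop=True)
    qvals = multipletests(windows["p_value"].to_numpy(), method="fdr_bh")[1]
    sig = windows[
        (windows["n_cpg"] >= min_cpg)
        & (windows["fold_change"] >= min_fold)
        & (windows["p_value"] <= p_max)
    ].copy()
    sig["q_value"] = qvals[sig.index.to_numpy()]
    if len(sig) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)

    joint = None
    if pooled_a is not None and pooled_b is not None:
        joint = _joint_sites(pooled_a, pooled_b, context, min_total)

    dmrs = []
    sig = sig.sort_values(["chrom", "start", "end"], kind="stable")
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=True):
        cur = None
        members: list[pd.Series] = []
        for _, w in grp.iterrows():
            if cur is None:
                cur = [w["start"], w["end"]]
                members = [w]
            elif w["start"] <= cur[1]:  # overlap or book-ended
                cur[1] = max(cur[1], w["end"])
                members.append(w)
            else:
                dmrs.append(_merge_region(chrom, cur, members, direction,
                                          context, joint))
                cur = [w["start"], w["end"]]
                members = [w]
        if cur is not None:
            dmrs.append(_merge_region(chrom, cur, members, direction,
                                      context, joint))
    out = pd.DataFrame(dmrs, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _merge_region(chrom, span, members, direction, context, joint):
    start, end = int(span[0]), int(span[1])
    if joint is not None:
        j = joint[(joint["chrom"] == chrom)
                  & (joint["pos"] >= start) & (joint["pos"] < end)]
        meth_a, tot_a = int(j["meth_a"].sum()), int(j["total_a"].sum())
        meth_b, tot_b = int(j["meth_b"].sum()), int(j["total_b"].sum())
        n_cpg = int(len(j))
    else:
        # approximate from constituent windows' non-overlapping pieces
        meth_a = tot_a = meth_b = tot_b = n_cpg = 0
        covered = -1
        for w in members:
            if w["start"] >= covered:
                meth_a += int(w["meth_a"]); tot_a += int(w["total_a"])
                meth_b += int(w["meth_b"]); tot_b += int(w["total_b"])
                n_cpg += int(w["n_cpg"])
                covered = int(w["end"])
    la = meth_a / tot_a if tot_a else 0.0
    lb = meth_b / tot_b if tot_b else 0.0
    return {
        "chrom": chrom, "start": start, "end": end, "n_cpg": n_cpg,
        "meth_a": meth_a, "total_a": tot_a, "meth_b": meth_b, "total_b": tot_b,
        "level_a": la, "level_b": lb,
        "fold_change": fold_change(la, lb),
        "p_value": fisher_two_sided(meth_a, tot_a - meth_a,
                                    meth_b, tot_b - meth_b),
        "direction": direction, "context": context,
        "n_windows": len(members),
        "q_value": float(min(w["q_value"] for w in members)),
    }


def find_dmrs(
    tables_a: list[pd.DataFrame],
    tables_b: list[pd.DataFrame],
    context: str = "CG",
    width: int = 1000,
    step: int = 500,
    min_cpg: int = 5,
    min_total: int = 4,
    p_max: float = 0.05,
    min_fold: float = 2.0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end DMR calling: pool, scan, filter, merge.

    Returns (dmrs, windows).
    """
    windows = scan_windows(
        tables_a, tables_b, context=context, width=width, step=step,
        min_cpg=min_cpg, min_total=min_total, chrom_lengths=chrom_lengths,
    )
    pa = pool_replicates(tables_a, context)
    pb = pool_replicates(tables_b, context)
    dmrs = call_dmrs(
        windows, p_max=p_max, min_fold=min_fold, min_cpg=min_cpg,
        context=context, pooled_a=pa, pooled_b=pb, min_total=min_total,
    )
    return dmrs, windows


# ---------------------------------------------------------------------------
# annotation of DMRs


@dataclass(frozen=True)
class DMGAssignment:
    """One gene x one overlapping DMR, labelled by the gene feature hit."""

    gene_id: str
    dmr_index: int
    feature: str  # promoter | exon | intron | downstream


def annotate_dmrs(
    dmrs: pd.DataFrame, annotation: AnnotationSet
) -> list[DMGAssignment]:
    """Assign DMRs to gene features by half-open interval intersection.

    A DMR is assigned to every gene feature it overlaps by >= 1 bp; one gene
    can collect several assignments.  DMRs on chromosomes absent from the
    annotation are left unannotated.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        ps, pe = g.promoter
        if ps < pe:
            tree.addi(ps, pe, (g.gene_id, "promoter"))
        ds, de = g.downstream_region
        if ds < de:
            tree.addi(ds, de, (g.gene_id, "downstream"))
        for s, e in g.exons:
            tree.addi(s, e, (g.gene_id, "exon"))
        for s, e in g.introns:
            tree.addi(s, e, (g.gene_id, "intron"))

    out: list[DMGAssignment] = []
    for i, row in enumerate(dmrs.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = {(d[0], d[1]) for iv in tree.overlap(row.start, row.end)
                for d in [iv.data]}
        for gene_id, feature in sorted(hits):
            out.append(DMGAssignment(gene_id=gene_id, dmr_index=i, feature=feature))
    return out


def promoter_dmgs(assignments: list[DMGAssignment]) -> set[str]:
    """Genes with >= 1 DMR overlapping their promoter, each counted once."""
    return {a.gene_id for a in assignments if a.feature == "promoter"}


def dmg_table(assignments: list[DMGAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": a.gene_id, "dmr_index": a.dmr_index, "feature": a.feature}
         for a in assignments],
        columns=["gene_id", "dmr_index", "feature"],
    )
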