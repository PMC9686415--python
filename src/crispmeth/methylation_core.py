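"""Site-level and genome-level methylation statistics.

The central quantity is the methylation level Rm = Nm / (Nm + Nnm): the
number of reads supporting methylation at a cytosine divided by all reads
covering it.  Region- and genome-level statistics pool read counts before
dividing, so a deeply covered site weighs more than a shallow one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def methylation_level(meth_count: int, total_count: int) -> float:
    """Per-site methylation level: methylated reads over total reads."""
    if total_count < 1:
        raise ValueError("methylation level undefined at zero coverage")
    if meth_count < 0 or meth_count > total_count:
        raise ValueError("need 0 <= meth_count <= total_count")
    return meth_count / total_count


def pooled_level(meth: np.ndarray, total: np.ndarray) -> float:
    """Pooled level over sites/replicates: sum(meth) / sum(total)."""
    t = int(np.sum(total))
    if t == 0:
        raise ValueError("pooled level undefined at zero total coverage")
    return float(np.sum(meth)) / t


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Classify the cytosine at ``pos`` into CG / CHG / CHH (H = A, C or T).

    ``pos`` is the 0-based forward-strand offset.  On '+' the base there must
    be C and the two downstream bases decide the context; on '-' the forward
    base must be G and the classification applies to the reverse complement.
    Within 2 bp of a contig end, where the downstream bases run out, the
    context is 'NA'; an ambiguous downstream base (N) is also 'NA'.
    """
    if strand == "+":
        if pos < 0 or pos >= len(reference) or reference[pos] != "C":
            raise ValueError(f"base at +{pos} is not C")
        nxt = reference[pos + 1] if pos + 1 < len(reference) else None
        nxt2 = reference[pos + 2] if pos + 2 < len(reference) else None
    elif strand == "-":
        if pos < 0 or pos >= len(reference) or reference[pos] != "G":
            raise ValueError(f"base at -{pos} (forward G) is not present")
        nxt = reference[pos - 1].translate(COMPLEMENT) if pos - 1 >= 0 else None
        nxt2 = reference[pos - 2].translate(COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt is None:
        return "NA"
    if nxt == "G":
        return "CG"
    if nxt not in "ACT":
        return "NA"
    if nxt2 is None:
        return "NA"
    if nxt2 == "G":
        return "CHG"
    if nxt2 in "ACT":
        return "CHH"
    return "NA"


def classify_contexts(sequence: str) -> pd.DataFrame:
    """Vectorized context classification of every cytosine in a sequence.

    Returns a DataFrame with columns ``pos, strand, context`` covering all
    forward-strand C's and reverse-strand C's (forward G's), contexts in
    {CG, CHG, CHH, NA}.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_h = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("T"))
    n = len(arr)

    def _ctx(pos: np.ndarray, nxt_g, nxt_h, nxt2_g, nxt2_h) -> np.ndarray:
        ctx = np.full(len(pos), "NA", dtype="<U3")
        ctx[nxt_g] = "CG"
        ctx[nxt_h & nxt2_g] = "CHG"
        ctx[nxt_h & nxt2_h] = "CHH"
        return ctx

    # forward strand: look at pos+1, pos+2
    fpos = np.flatnonzero(is_c)
    f1 = fpos + 1
    f2 = fpos + 2
    f1_ok = f1 < n
    f2_ok = f2 < n
    fg1 = np.zeros(len(fpos), bool); fh1 = np.zeros(len(fpos), bool)
    fg2 = np.zeros(len(fpos), bool); fh2 = np.zeros(len(fpos), bool)
    fg1[f1_ok] = is_g[f1[f1_ok]]; fh1[f1_ok] = is_h[f1[f1_ok]]
    fg2[f2_ok] = is_g[f2[f2_ok]]; fh2[f2_ok] = is_h[f2[f2_ok]]
    fctx = _ctx(fpos, fg1, fh1, fg2, fh2)

    # reverse strand: cytosine sits where forward shows G; downstream on the
    # reverse sense is pos-1, pos-2, with G<->C complementarity.
    rpos = np.flatnonzero(is_g)
    r1 = rpos - 1
    r2 = rpos - 2
    r1_ok = r1 >= 0
    r2_ok = r2 >= 0
    rg1 = np.zeros(len(rpos), bool); rh1 = np.zeros(len(rpos), bool)
    rg2 = np.zeros(len(rpos), bool); rh2 = np.zeros(len(rpos), bool)
    # complement: forward C -> reverse G; forward A/G/T -> reverse T/C/A (H)
    rg1[r1_ok] = is_c[r1[r1_ok]]
    rh1[r1_ok] = ~is_c[r1[r1_ok]] & (arr[r1[r1_ok]] != ord("N"))
    rg2[r2_ok] = is_c[r2[r2_ok]]
    rh2[r2_ok] = ~is_c[r2[r2_ok]] & (arr[r2[r2_ok]] != ord("N"))
    rctx = _ctx(rpos, rg1, rh1, rg2, rh2)

    return pd.DataFrame(
        {
            "pos": np.concatenate([fpos, rpos]),
            "strand": np.concatenate(
                [np.full(len(fpos), "+"), np.full(len(rpos), "-")]
            ),
            "context": np.concatenate([fctx, rctx]),
        }
    ).sort_values(["pos", "strand"], kind="stable", ignore_index=True)


@dataclass
class MethylomeSummary:
    """Per-context methylated-cytosine counts, shares and mean levels."""

    sample_id: str
    mc_counts: dict = field(default_factory=dict)      # context -> n methylated C
    shares: dict = field(default_factory=dict)         # context -> % of all mC
    mean_levels: dict = field(default_factory=dict)    # context -> pooled level
    n_sites_covered: int = 0
    total_mc: int = 0


@dataclass
class AlignmentSummary:
    """Read-alignment bookkeeping: counts and derived percentage rates."""

    clean_reads: int
    mapped_reads: int
    uniquely_mapped_reads: int
    mapping_rate: float
    unique_rate: float
    conversion_rate: float | None = None


def context_shares(counts: dict[str, int]) -> dict[str, float]:
    """Percentage of all methylated cytosines per context, 2 decimals."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no methylated cytosines: shares undefined")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def summarize_methylome(
    records: pd.DataFrame,
    sample_id: str = "",
    min_total: int = 4,
    min_meth_evidence: int = 1,
    conversion_failure_rate: float | None = None,
    alpha: float = 0.05,
) -> MethylomeSummary:
    """Count methylated cytosines per context and their percentage shares.

    A covered site (total >= ``min_total``) counts as methylated when
    meth >= ``min_meth_evidence``.  If ``conversion_failure_rate`` is given,
    a one-sided binomial test against that failure rate is applied instead,
    with Benjamini-Hochberg control at ``alpha`` — the rigorous calling rule
    for data with appreciable incomplete conversion.
    """
    df = records[records["total"] >= min_total]
    df = df[df["context"].isin(["CG", "CHG", "CHH"])]
    if conversion_failure_rate is not None:
        from scipy.stats import binom
        from statsmodels.stats.multitest import multipletests

        cand = df[df["meth"] >= 1]
        if len(cand):
            p = binom.sf(
                cand["meth"].to_numpy() - 1,
                cand["total"].to_numpy(),
                conversion_failure_rate,
            )
            sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
            meth_mask = pd.Series(False, index=df.index)
            meth_mask.loc[cand.index[sig]] = True
        else:
            meth_mask = pd.Series(False, index=df.index)
    else:
        meth_mask = df["meth"] >= min_meth_evidence
    mdf = df[meth_mask]
    counts = {c: int((mdf["context"] == c).sum()) for c in ("CG", "CHG", "CHH")}
    summary = MethylomeSummary(
        sample_id=sample_id,
        mc_counts=counts,
        n_sites_covered=int(len(df)),
        total_mc=sum(counts.values()),
    )
    summary.shares = context_shares(counts) if summary.total_mc else {}
    for c in ("CG", "CHG", "CHH"):
        sub = df[df["context"] == c]
        if sub["total"].sum() > 0:
            summary.mean_levels[c] = pooled_level(
                sub["meth"].to_numpy(), sub["total"].to_numpy()
            )
    return summary


def summarize_from_counts(mcg: int, mchg: int, mchh: int) -> dict[str, float]:
    """Context shares straight from per-context methylated-C counts."""
    return context_shares({"CG": mcg, "CHG": mchg, "CHH": mchh})


def conversion_rate(lambda_records: pd.DataFrame) -> float:
    """Bisulfite conversion rate from the unmethylated lambda spike-in.

    The phage genome carries no methylation, so any methylated call there is
    a conversion failure: rate = 100 * (1 - pooled methylation of lambda).
    """
    total = int(lambda_records["total"].sum())
    if total == 0:
        raise ValueError("lambda control has zero coverage")
    meth = int(lambda_records["meth"].sum())
    return 100.0 * (1.0 - meth / total)


def alignment_rates(
    clean_reads: int, mapped_reads: int, uniquely_mapped_reads: int,
    conversion_rate: float | None = None,
) -> AlignmentSummary:
    """Mapping and unique-mapping percentage rates from read counts."""
    if not (0 <= uniquely_mapped_reads <= mapped_reads <= clean_reads):
        raise ValueError(
            "need uniquely_mapped <= mapped <= clean, all non-negative"
        )
    if clean_reads == 0:
        raise ValueError("zero clean reads")
    return AlignmentSummary(
        clean_reads=clean_reads,
        mapped_reads=mapped_reads,
        uniquely_mapped_reads=uniquely_mapped_reads,
        mapping_rate=round(100.0 * mapped_reads / clean_reads, 2),
        unique_rate=round(100.0 * uniquely_mapped_reads / clean_reads, 2),
        conversion_rate=conversion_rate,
    )
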