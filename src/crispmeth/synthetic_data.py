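"""Seeded generator of a toy methylome study.

Emulates the structure of a two-group (3 + 3 replicate) WGBS comparison of
fish muscle: a small genome with CpG-enriched island patches, non-overlapping
multi-exon genes, per-sample per-cytosine call tables with a CG-dominated
methylation landscape, planted promoter DMRs, an unmethylated lambda
spike-in, and an expression table whose planted differential genes are
anti-correlated with their promoter methylation change.

Modelling choices
-----------------
* Per-site true levels are a two-component mixture: a site is "methylated"
  with probability baseline/0.95 and then draws its level from a Beta with
  mean 0.95; otherwise its level is exactly 0.  The mixture mean therefore
  equals the configured per-context baseline while the landscape stays
  bimodal, as real methylomes are.
* Replicate noise is beta-binomial: replicate level ~ Beta around the site's
  true level with overdispersion ``dispersion``; coverage ~ Poisson;
  methylated reads ~ Binomial(coverage, replicate level).
* The toy genome is NOT CpG-depleted: CpG dinucleotides are stamped in at
  ~0.035/bp genome-wide (more inside islands) so that CG-context sites make
  up ~30% of cytosines and >90% of methylated cytosines fall in CG context,
  the regime seen in fish muscle methylomes.
* Planted DMRs sit in promoters on a dedicated intermediate base level
  (default 0.45) and shift one group's mean by +-``dmr_effect`` (clipped to
  [0, 1]); at an intermediate base both shift signs remain detectable under
  a two-fold-change rule.

Every function draws only from the numpy Generator it is handed (or derives
one from ``config.seed``), so a fixed seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    GeneModel,
    write_bed_intervals,
    write_cytosine_table,
    write_fasta,
    write_gtf,
)
from .methylation_core import classify_contexts

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the package's desk-scale
    stand-in for the real design (2 groups x 3 replicates, CG-dominated
    methylome, ~20x coverage)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_replicates: int = 3
    group_a: str = "CGC"
    group_b: str = "OGC"
    # mean methylation level per context
    baseline_cg: float = 0.80
    baseline_chg: float = 0.02
    baseline_chh: float = 0.03
    island_cg_level: float = 0.92
    meth_site_level: float = 0.95     # mean level of the methylated component
    meth_site_concentration: float = 30.0
    dispersion: float = 0.02          # beta-binomial replicate overdispersion
    mean_coverage: float = 20.0
    # genome composition
    base_probs: tuple = (0.3, 0.2, 0.2, 0.3)  # A, C, G, T outside islands
    cpg_stamp_rate: float = 0.035
    island_stamp_rate: float = 0.08
    island_promoter_fraction: float = 0.3
    n_intergenic_islands: int = 20
    island_length_range: tuple = (500, 1000)
    # planted effects
    n_planted_dmrs: int = 50
    dmr_effect: float = 0.5           # |delta methylation| of planted DMRs
    dmr_base_level: float = 0.45
    p_anticorrelated: float = 0.8
    deg_log2fc_range: tuple = (1.5, 3.0)
    null_log2fc_sd: float = 0.3
    # lambda spike-in
    lambda_length: int = 48_502
    lambda_failure_rate: float = 0.0095
    # annotation spans
    upstream_span: int = 2000
    downstream_span: int = 2000

    def validate(self) -> None:
        fracs = {
            "baseline_cg": self.baseline_cg, "baseline_chg": self.baseline_chg,
            "baseline_chh": self.baseline_chh, "island_cg_level": self.island_cg_level,
            "meth_site_level": self.meth_site_level, "dispersion": self.dispersion,
            "cpg_stamp_rate": self.cpg_stamp_rate,
            "island_stamp_rate": self.island_stamp_rate,
            "island_promoter_fraction": self.island_promoter_fraction,
            "dmr_effect": self.dmr_effect, "dmr_base_level": self.dmr_base_level,
            "p_anticorrelated": self.p_anticorrelated,
            "lambda_failure_rate": self.lambda_failure_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_planted_dmrs > self.n_genes:
            raise ValueError("cannot plant more DMRs than genes")

    def sample_ids(self) -> dict[str, list[str]]:
        return {
            self.group_a: [f"{self.group_a}{i + 1}" for i in range(self.n_replicates)],
            self.group_b: [f"{self.group_b}{i + 1}" for i in range(self.n_replicates)],
        }


@dataclass
class TruthSet:
    """Ledger of what was planted, for recovery scoring."""

    dmrs: list = field(default_factory=list)   # dicts: chrom,start,end,gene_id,...
    degs: list = field(default_factory=list)   # dicts: gene_id, log2_fc, fdr, ...
    lambda_failure_rate: float = 0.0

    def dmr_intervals(self) -> list[tuple[str, int, int]]:
        return [(d["chrom"], d["start"], d["end"]) for d in self.dmrs]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# genome


def _random_partition(rng, total: int, parts: int, min_size: int) -> list[int]:
    """Split ``total`` into ``parts`` positive chunks of >= min_size."""
    free = total - parts * min_size
    if free < 0:
        raise ValueError("interval too short to partition")
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    chunks = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(c) + min_size for c in chunks]


def _place_genes(rng, config: SimulationConfig) -> list[GeneModel]:
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    margin = config.upstream_span + config.downstream_span + 1000
    genes: list[GeneModel] = []
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        max_len = slot - margin
        if max_len < 300:
            raise ValueError(
                "genes cannot fit: increase chrom_length or reduce n_genes"
            )
        chrom = f"chr{ci + 1}"
        for si in range(n_here):
            s0 = si * slot
            glen = int(rng.integers(min(1500, max_len), max_len + 1))
            gstart = s0 + config.upstream_span + 500 + int(rng.integers(0, 500))
            n_ex = int(rng.integers(2, 6)) if glen >= 600 else 1
            seg_lens = _random_partition(rng, glen, 2 * n_ex - 1, 50)
            exons = []
            off = gstart
            for k, L in enumerate(seg_lens):
                if k % 2 == 0:
                    exons.append((off, off + L))
                off += L
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}", chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons), chrom_length=config.chrom_length,
                    upstream_span=config.upstream_span,
                    downstream_span=config.downstream_span,
                )
            )
    return genes


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], AnnotationSet]:
    """Toy genome: random sequence, CpG-island patches, non-overlapping genes.

    Islands are realized both as elevated-CpG sequence patches and as
    recorded intervals in the returned annotation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _place_genes(rng, config)
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }

    # island intervals: at a fraction of gene TSSs plus intergenic patches
    islands: list[tuple[str, int, int]] = []
    lo, hi = config.island_length_range
    for g in genes:
        if rng.random() < config.island_promoter_fraction:
            L = int(rng.integers(lo, hi + 1))
            s = max(0, g.tss - L // 2)
            islands.append((g.chrom, s, min(s + L, config.chrom_length)))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append(
            (g.promoter[0], g.downstream_region[1])
        )
    for _ in range(config.n_intergenic_islands):
        chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
        L = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, config.chrom_length - L))
        if any(s < e and s + L > b for b, e in gene_spans.get(chrom, [])):
            continue  # keep intergenic islands out of gene territory
        islands.append((chrom, s, s + L))
    islands.sort()

    sequences: dict[str, str] = {}
    for chrom, L in chrom_lengths.items():
        seq = rng.choice(BASES, size=L, p=np.asarray(config.base_probs))
        island_mask = np.zeros(L, dtype=bool)
        for c, s, e in islands:
            if c == chrom:
                island_mask[s:e] = True
        # islands get a GC-balanced background before CpG stamping
        n_isl = int(island_mask.sum())
        if n_isl:
            seq[island_mask] = rng.choice(BASES, size=n_isl)
        stamp_p = np.full(L, config.cpg_stamp_rate)
        stamp_p[island_mask] = config.island_stamp_rate
        pos = np.flatnonzero(rng.random(L) < stamp_p)
        pos = pos[pos < L - 1]
        if len(pos):
            keep = [int(pos[0])]
            for p in pos[1:]:
                if p - keep[-1] >= 2:
                    keep.append(int(p))
            kp = np.asarray(keep)
            seq[kp] = ord("C")
            seq[kp + 1] = ord("G")
        sequences[chrom] = seq.tobytes().decode("ascii")

    ann = AnnotationSet(
        genes=genes, cpg_islands=islands, chrom_lengths=chrom_lengths
    )
    return sequences, ann


# ---------------------------------------------------------------------------
# methylomes


def _beta_around(rng, mean: np.ndarray, concentration: float) -> np.ndarray:
    """Beta draws with the given mean; mean 0 or 1 passes through exactly."""
    out = np.asarray(mean, dtype=float).copy()
    interior = (out > 0.0) & (out < 1.0)
    if interior.any():
        m = out[interior]
        out[interior] = rng.beta(m * concentration, (1.0 - m) * concentration)
    return out


def simulate_methylomes(
    sequences: dict[str, str],
    annotation: AnnotationSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Per-sample call tables with planted promoter DMRs, plus the truth set.

    Contexts are classified from the actual simulated sequence, so the
    classifier is exercised end to end.  Sites with zero simulated coverage
    are absent from the output, as in real call files.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # choose genes to plant, with direction of the group-B shift
    plantable = list(annotation.genes)
    idx = rng.choice(len(plantable), size=config.n_planted_dmrs, replace=False)
    truth = TruthSet(lambda_failure_rate=config.lambda_failure_rate)
    planted: dict[str, list[tuple[int, int, float]]] = {}
    clipped = False
    for i in sorted(int(j) for j in idx):
        g = plantable[i]
        s, e = g.promoter
        sign = 1.0 if rng.random() < 0.5 else -1.0
        level_b = config.dmr_base_level + sign * config.dmr_effect
        if level_b < 0.0 or level_b > 1.0:
            clipped = True
            level_b = float(np.clip(level_b, 0.0, 1.0))
        planted.setdefault(g.chrom, []).append((s, e, level_b))
        truth.dmrs.append(
            {
                "chrom": g.chrom, "start": s, "end": e, "gene_id": g.gene_id,
                "level_a": config.dmr_base_level, "level_b": level_b,
                "direction": "hyper_in_A"
                if level_b < config.dmr_base_level else "hypo_in_A",
            }
        )
    if clipped:
        warnings.warn("planted DMR effect clipped to [0, 1]")

    f_cg = config.baseline_cg / config.meth_site_level
    f_chg = config.baseline_chg / config.meth_site_level
    f_chh = config.baseline_chh / config.meth_site_level
    f_island = config.island_cg_level / config.meth_site_level
    conc = config.meth_site_concentration
    rep_conc = (1.0 - config.dispersion) / config.dispersion

    ids = config.sample_ids()
    frames: dict[str, list[pd.DataFrame]] = {
        sid: [] for group in ids.values() for sid in group
    }
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        ctx = classify_contexts(seq)
        ctx = ctx[ctx["context"] != "NA"].reset_index(drop=True)
        pos = ctx["pos"].to_numpy()
        n = len(ctx)

        # per-site methylated fraction by context / island status
        frac = np.zeros(n)
        ctx_arr = ctx["context"].to_numpy()
        frac[ctx_arr == "CG"] = f_cg
        frac[ctx_arr == "CHG"] = f_chg
        frac[ctx_arr == "CHH"] = f_chh
        island_mask = np.zeros(n, dtype=bool)
        for c, s, e in annotation.cpg_islands:
            if c == chrom:
                island_mask |= (pos >= s) & (pos < e)
        frac[island_mask & (ctx_arr == "CG")] = f_island

        is_meth = rng.random(n) < frac
        level_a = np.zeros(n)
        level_a[is_meth] = _beta_around(
            rng, np.full(int(is_meth.sum()), config.meth_site_level), conc
        )
        level_b = level_a.copy()
        # planted promoter DMRs override CG sites inside the interval
        for s, e, lb in planted.get(chrom, []):
            m = (pos >= s) & (pos < e) & (ctx_arr == "CG")
            level_a[m] = _beta_around(
                rng, np.full(int(m.sum()), config.dmr_base_level), conc
            )
            level_b[m] = np.clip(
                level_a[m] + (lb - config.dmr_base_level), 0.0, 1.0
            )

        for group, site_level in ((config.group_a, level_a), (config.group_b, level_b)):
            for sid in ids[group]:
                rep_level = _beta_around(rng, site_level, rep_conc)
                cov = rng.poisson(config.mean_coverage, size=n)
                meth = rng.binomial(cov, rep_level)
                covered = cov > 0
                frames[sid].append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos[covered],
                            "strand": ctx["strand"].to_numpy()[covered],
                            "context": ctx_arr[covered],
                            "meth": meth[covered],
                            "total": cov[covered],
                        }
                    )
                )

    samples = {
        sid: pd.concat(parts, ignore_index=True) for sid, parts in frames.items()
    }
    return samples, truth


def simulate_lambda(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Call table for the unmethylated lambda spike-in.

    Every cytosine is truly unmethylated; apparent methylated reads arise
    only from bisulfite conversion failure.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq_arr = rng.choice(BASES, size=config.lambda_length)
    seq = seq_arr.tobytes().decode("ascii")
    ctx = classify_contexts(seq)
    ctx = ctx[ctx["context"] != "NA"].reset_index(drop=True)
    n = len(ctx)
    cov = rng.poisson(config.mean_coverage, size=n)
    meth = rng.binomial(cov, config.lambda_failure_rate)
    covered = cov > 0
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": ctx["pos"].to_numpy()[covered],
            "strand": ctx["strand"].to_numpy()[covered],
            "context": ctx["context"].to_numpy()[covered],
            "meth": meth[covered],
            "total": cov[covered],
        }
    )


def simulate_expression(
    annotation: AnnotationSet,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expression table (gene_id, log2_fc, fdr) linked to planted DMRs.

    Genes with a planted promoter DMR become differential with an effect
    whose sign opposes the methylation change with probability
    ``p_anticorrelated`` (promoter hypomethylation -> higher expression).
    log2_fc is group A relative to group B.  Other genes are null: small
    fold changes and FDR well above the DEG threshold.

    Appends the planted DEGs to ``truth.degs``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    planted_dir = {d["gene_id"]: d["direction"] for d in truth.dmrs}
    lo, hi = config.deg_log2fc_range
    rows = []
    for g in annotation.genes:
        gid = g.gene_id
        if gid in planted_dir:
            mag = float(rng.uniform(lo, hi))
            canonical = bool(rng.random() < config.p_anticorrelated)
            # hypo_in_A + canonical -> expression up in A (positive log2_fc)
            meth_up_in_a = planted_dir[gid] == "hyper_in_A"
            sign = -1.0 if meth_up_in_a == canonical else 1.0
            log2_fc = sign * mag
            fdr = float(10.0 ** rng.uniform(-6.0, -4.0))
            truth.degs.append(
                {
                    "gene_id": gid, "log2_fc": log2_fc, "fdr": fdr,
                    "anticorrelated": canonical,
                }
            )
        else:
            log2_fc = float(rng.normal(0.0, config.null_log2fc_sd))
            fdr = float(rng.uniform(0.01, 1.0))
        rows.append({"gene_id": gid, "log2_fc": log2_fc, "fdr": fdr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimBundle:
    """Everything one seeded run of the generator produces."""

    config: SimulationConfig
    sequences: dict
    annotation: AnnotationSet
    samples: dict          # sample id -> call table
    lambda_calls: pd.DataFrame
    expression: pd.DataFrame
    truth: TruthSet

    def group_tables(self) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
        ids = self.config.sample_ids()
        return (
            [self.samples[s] for s in ids[self.config.group_a]],
            [self.samples[s] for s in ids[self.config.group_b]],
        )


def simulate_all(config: SimulationConfig) -> SimBundle:
    """Run the four generators off one seeded RNG, in a fixed order."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sequences, annotation = simulate_genome(config, rng)
    samples, truth = simulate_methylomes(sequences, annotation, config, rng)
    lam = simulate_lambda(config, rng)
    expr = simulate_expression(annotation, truth, config, rng)
    return SimBundle(config, sequences, annotation, samples, lam, expr, truth)


def write_bundle(bundle: SimBundle, out_dir) -> dict[str, str]:
    """Write the bundle to disk; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_fasta(bundle.sequences, out / "genome.fa")
    paths["genome"] = str(out / "genome.fa")
    write_gtf(bundle.annotation.genes, out / "genes.gtf")
    paths["genes"] = str(out / "genes.gtf")
    write_bed_intervals(bundle.annotation.cpg_islands, out / "islands.bed")
    paths["islands"] = str(out / "islands.bed")
    for sid, df in bundle.samples.items():
        p = out / f"{sid}.cgmap.tsv"
        write_cytosine_table(df, p)
        paths[sid] = str(p)
    write_cytosine_table(bundle.lambda_calls, out / "lambda.cgmap.tsv")
    paths["lambda"] = str(out / "lambda.cgmap.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    paths["expression"] = str(out / "expression.tsv")
    bundle.truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=2, default=list)
        fh.write("\n")
    paths["config"] = str(out / "sim_config.json")
    return paths
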