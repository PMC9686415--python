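"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are 0-based half-open internally; 1-based external dialects
(CGmap, GTF) are converted at the I/O boundary and nowhere else.

Per-cytosine methylation calls are carried as a pandas DataFrame with columns
``chrom, pos, strand, context, meth, total`` ("call table"), one row per
reference cytosine, where ``pos`` is the 0-based forward-strand offset of the
cytosine (for a minus-strand cytosine this is the position of the G on the
forward strand).  :class:`CytosineRecord` is the scalar view of one row.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]
CONTEXTS = ("CG", "CHG", "CHH", "NA")

#: 7 metagene features in transcription order.
GENE_FEATURES = (
    "upstream",
    "first_exon",
    "first_intron",
    "internal_exons",
    "internal_introns",
    "last_exon",
    "downstream",
)


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class CytosineRecord:
    """One reference cytosine with its bisulfite read support.

    ``meth`` counts reads reporting methylation (unconverted C), ``total``
    all reads covering the site, so the site-level methylation is
    ``meth / total``.
    """

    chrom: str
    pos: int  # 0-based forward-strand offset
    strand: str
    context: str
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.pos < 0 or self.meth < 0 or self.total < 0:
            raise ValueError("negative position or count")
        if self.meth > self.total:
            raise ValueError(
                f"meth_count {self.meth} exceeds total_count {self.total}"
            )


def validate_calls(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a call table in place and return it.

    Raises :class:`FormatError` on the first invariant violation.
    """
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table missing columns {missing}")
    if len(df) == 0:
        return df
    if (df["meth"] < 0).any() or (df["total"] < 0).any():
        raise FormatError("negative read counts")
    bad = df["meth"] > df["total"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"meth_count > total_count at {df['chrom'].iloc[i]}:{df['pos'].iloc[i]}"
        )
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    if not df["context"].isin(CONTEXTS).all():
        bad_ctx = sorted(set(df["context"]) - set(CONTEXTS))
        raise FormatError(f"unknown context(s) {bad_ctx}")
    return df


def iter_records(df: pd.DataFrame) -> Iterator[CytosineRecord]:
    """Yield rows of a call table as :class:`CytosineRecord` objects."""
    for row in df.itertuples(index=False):
        yield CytosineRecord(
            str(row.chrom), int(row.pos), str(row.strand), str(row.context),
            int(row.meth), int(row.total),
        )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # 1e-9 guards exact .5 ties against binary representation of the
    # decimal fraction text (e.g. 0.35 * 10 = 3.4999999999999996)
    return np.floor(x + 0.5 + 1e-9).astype(np.int64)


def read_cytosine_table(path, dialect: str = "cgmap") -> pd.DataFrame:
    """Read a per-cytosine methylation call file into a call table.

    dialect ``cgmap``
        Tab-separated, 1-based: ``chrom  nucleotide  pos  context  dinuc
        level  meth_count  total_count``.  ``nucleotide`` C means the
        cytosine is on the forward strand, G on the reverse.
    dialect ``bedgraph_pair``
        Tab-separated, 0-based half-open: ``chrom  start  end  fraction
        coverage  strand  context``; the methylated count is reconstructed
        as round-half-up of ``fraction * coverage``.

    Returns the table sorted by (chrom, pos) and validated.
    """
    path = Path(path)
    if dialect == "cgmap":
        names = ["chrom", "nuc", "pos1", "context", "dinuc", "level", "meth", "total"]
        usecols = [0, 1, 2, 3, 6, 7]
        try:
            raw = pd.read_csv(
                path, sep="\t", header=None, names=names, usecols=usecols,
                dtype={"chrom": str, "nuc": str, "context": str},
                comment="#",
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"{path}: malformed cgmap file: {exc}") from exc
        if len(raw) == 0:
            return pd.DataFrame(columns=CALL_COLUMNS)
        if not raw["nuc"].isin(["C", "G"]).all():
            i = int(np.flatnonzero(~raw["nuc"].isin(["C", "G"]).to_numpy())[0])
            raise FormatError(f"{path} line {i + 1}: nucleotide must be C or G")
        for col in ("pos1", "meth", "total"):
            vals = pd.to_numeric(raw[col], errors="coerce")
            if vals.isna().any():
                i = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise FormatError(f"{path} line {i + 1}: non-numeric {col!r} field")
            raw[col] = vals.astype(np.int64)
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos1"] - 1,  # 1-based dialect
                "strand": np.where(raw["nuc"] == "C", "+", "-"),
                "context": raw["context"],
                "meth": raw["meth"],
                "total": raw["total"],
            }
        )
    elif dialect == "bedgraph_pair":
        names = ["chrom", "start", "end", "fraction", "coverage", "strand", "context"]
        try:
            raw = pd.read_csv(
                path, sep="\t", header=None, names=names,
                dtype={"chrom": str, "strand": str, "context": str}, comment="#",
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"{path}: malformed bedGraph file: {exc}") from exc
        if len(raw) == 0:
            return pd.DataFrame(columns=CALL_COLUMNS)
        frac = pd.to_numeric(raw["fraction"], errors="coerce")
        cov = pd.to_numeric(raw["coverage"], errors="coerce")
        if frac.isna().any() or cov.isna().any():
            i = int(np.flatnonzero((frac.isna() | cov.isna()).to_numpy())[0])
            raise FormatError(f"{path} line {i + 1}: non-numeric fraction/coverage")
        if ((frac < 0) | (frac > 1)).any():
            raise FormatError(f"{path}: methylation fraction outside [0, 1]")
        total = cov.astype(np.int64)
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": pd.to_numeric(raw["start"]).astype(np.int64),
                "strand": raw["strand"].fillna("+"),
                "context": raw["context"].fillna("NA"),
                "meth": _round_half_up(frac.to_numpy() * total.to_numpy()),
                "total": total,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        validate_calls(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_cytosine_table(df: pd.DataFrame, path, dialect: str = "cgmap") -> None:
    """Write a call table in the given dialect (inverse of the reader)."""
    validate_calls(df)
    path = Path(path)
    if dialect == "cgmap":
        total = df["total"].to_numpy()
        level = np.divide(
            df["meth"].to_numpy(), total,
            out=np.zeros(len(df)), where=total > 0,
        )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "nuc": np.where(df["strand"] == "+", "C", "G"),
                "pos1": df["pos"] + 1,
                "context": df["context"],
                "dinuc": df["context"].map(lambda c: c[:2] if c != "NA" else "--"),
                "level": np.round(level, 6),
                "meth": df["meth"],
                "total": df["total"],
            }
        )
    elif dialect == "bedgraph_pair":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "fraction": np.round(
                    np.divide(
                        df["meth"].to_numpy(), df["total"].to_numpy(),
                        out=np.zeros(len(df)), where=df["total"].to_numpy() > 0,
                    ),
                    6,
                ),
                "coverage": df["total"],
                "strand": df["strand"],
                "context": df["context"],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene models and annotation


@dataclass(frozen=True)
class GeneModel:
    """One transcriptional unit decomposed into the seven metagene features.

    ``exons`` are half-open genomic intervals sorted by genomic start; feature
    accessors return intervals ordered 5'->3' in transcription orientation.
    The promoter is the ``upstream_span`` bp immediately 5' of the TSS on the
    gene's strand, clipped at chromosome bounds.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    chrom_length: int | None = None
    upstream_span: int = 2000
    downstream_span: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >=1 exon")
        ex = sorted(tuple(e) for e in self.exons)
        for (s, e) in ex:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
        for (a, b) in zip(ex, ex[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]) if a[1] < b[0]
        )

    def _clip(self, s: int, e: int) -> tuple[int, int]:
        s = max(0, s)
        if self.chrom_length is not None:
            e = min(e, self.chrom_length)
        return s, max(s, e)

    @property
    def promoter(self) -> tuple[int, int]:
        if self.strand == "+":
            return self._clip(self.start - self.upstream_span, self.start)
        return self._clip(self.end, self.end + self.upstream_span)

    @property
    def downstream_region(self) -> tuple[int, int]:
        if self.strand == "+":
            return self._clip(self.end, self.end + self.downstream_span)
        return self._clip(self.start - self.downstream_span, self.start)

    def features(self) -> dict[str, list[tuple[int, int]]]:
        """Genomic intervals of the 7 metagene features.

        Within each multi-interval feature the intervals are ordered in
        transcription orientation.  Single-exon genes have only
        ``upstream``, ``first_exon`` and ``downstream``.
        """
        tx = list(self.exons) if self.strand == "+" else list(self.exons)[::-1]
        introns = list(self.introns)
        tx_introns = introns if self.strand == "+" else introns[::-1]
        feats: dict[str, list[tuple[int, int]]] = {
            "upstream": [self.promoter],
            "first_exon": [tx[0]],
            "first_intron": [],
            "internal_exons": [],
            "internal_introns": [],
            "last_exon": [],
            "downstream": [self.downstream_region],
        }
        if len(tx) > 1:
            feats["first_intron"] = [tx_introns[0]] if tx_introns else []
            feats["internal_exons"] = tx[1:-1]
            feats["internal_introns"] = tx_introns[1:]
            feats["last_exon"] = [tx[-1]]
        return feats


@dataclass
class AnnotationSet:
    """Gene models plus optional CpG-island and repeat interval tracks."""

    genes: list[GeneModel] = field(default_factory=list)
    cpg_islands: list[tuple[str, int, int]] = field(default_factory=list)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def _gene_models_from_transcripts(
    transcripts: dict[str, dict],
    upstream_span: int,
    downstream_span: int,
    chrom_lengths: dict[str, int] | None,
) -> list[GeneModel]:
    """One representative transcript per gene: longest exonic span, ties to
    the lexicographically smallest transcript id."""
    by_gene: dict[str, list[tuple[int, str, dict]]] = {}
    for tid, t in transcripts.items():
        if not t["exons"]:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        span = sum(e - s for s, e in t["exons"])
        by_gene.setdefault(t["gene_id"], []).append((span, tid, t))
    genes = []
    for gid in sorted(by_gene):
        cands = by_gene[gid]
        cands.sort(key=lambda x: (-x[0], x[1]))
        _, tid, t = cands[0]
        cl = None
        if chrom_lengths:
            if t["chrom"] not in chrom_lengths:
                raise FormatError(f"unknown chromosome {t['chrom']!r} for gene {gid}")
            cl = chrom_lengths[t["chrom"]]
        genes.append(
            GeneModel(
                gene_id=gid, chrom=t["chrom"], strand=t["strand"],
                exons=tuple(sorted(t["exons"])), chrom_length=cl,
                upstream_span=upstream_span, downstream_span=downstream_span,
            )
        )
    return genes


def read_annotation(
    path,
    format: str = "gtf",
    upstream_span: int = 2000,
    downstream_span: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
    islands_bed=None,
    repeats_bed=None,
) -> AnnotationSet:
    """Read a GTF/GFF3 or BED12 gene annotation into an :class:`AnnotationSet`.

    GTF 1-based closed coordinates become internal 0-based half-open.  One
    representative transcript is kept per gene (longest exonic span).
    """
    path = Path(path)
    transcripts: dict[str, dict] = {}
    if format in ("gtf", "gff3"):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        for ex in db.features_of_type("exon"):
            tids = ex.attributes.get("transcript_id") or ex.attributes.get("Parent")
            if not tids:
                raise FormatError(f"{path}: exon without transcript_id/Parent")
            gids = ex.attributes.get("gene_id") or tids
            tid = tids[0]
            t = transcripts.setdefault(
                tid,
                {"gene_id": gids[0], "chrom": ex.seqid, "strand": ex.strand, "exons": []},
            )
            t["exons"].append((ex.start - 1, ex.end))  # 1-based closed -> half-open
    elif format == "bed12":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    raise FormatError(f"{path} line {ln}: BED12 needs 12 fields")
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise FormatError(f"{path} line {ln}: block count mismatch")
                exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
                transcripts[name] = {
                    "gene_id": name, "chrom": chrom, "strand": strand, "exons": exons,
                }
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    genes = _gene_models_from_transcripts(
        transcripts, upstream_span, downstream_span, chrom_lengths
    )
    ann = AnnotationSet(genes=genes, chrom_lengths=dict(chrom_lengths or {}))
    if islands_bed is not None:
        ann.cpg_islands = read_bed_intervals(islands_bed)
    if repeats_bed is not None:
        ann.repeats = read_bed_intervals(repeats_bed)
    return ann


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns as sorted half-open intervals."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path} line {ln}: BED needs >=3 fields")
            out.append((f[0], int(f[1]), int(f[2])))
    return sorted(out)


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# DMR tables

DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tneg_log10_p\tstrand\t"
    "fold_change\tlevel_a\tlevel_b\tn_cpg\tdirection\tcontext\tn_windows"
)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write called DMRs as BED6+ (0-based half-open).

    Column 5 is -log10(p) (capped at 308); extra columns carry fold change,
    the two pooled group levels, covered-CpG count, direction, context and
    the number of merged windows.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(DMR_BED_HEADER + "\n")
        for i, row in enumerate(dmrs.itertuples(index=False), 1):
            p = max(float(row.p_value), 1e-308)
            score = round(-np.log10(p), 6)
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tDMR{i:05d}\t{score}\t.\t"
                f"{row.fold_change:.6g}\t{row.level_a:.6f}\t{row.level_b:.6f}\t"
                f"{row.n_cpg}\t{row.direction}\t{row.context}\t{row.n_windows}\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    """Read a file written by :func:`write_dmr_bed` back into a DMR table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 13:
                raise FormatError(f"{path} line {ln}: expected 13 fields")
            rows.append(
                {
                    "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                    "p_value": 10.0 ** (-float(f[4])),
                    "fold_change": float(f[6]), "level_a": float(f[7]),
                    "level_b": float(f[8]), "n_cpg": int(f[9]),
                    "direction": f[10], "context": f[11], "n_windows": int(f[12]),
                }
            )
    cols = ["chrom", "start", "end", "n_cpg", "level_a", "level_b",
            "fold_change", "p_value", "direction", "context", "n_windows"]
    return pd.DataFrame(rows, columns=cols)


def write_report_tables(summary: dict, path_prefix) -> None:
    """Write a run summary as JSON plus a flat TSV of scalar fields."""
    path_prefix = Path(path_prefix)
    with open(path_prefix.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    flat = {
        k: v for k, v in summary.items() if isinstance(v, (int, float, str, bool))
    }
    pd.DataFrame([flat]).to_csv(path_prefix.with_suffix(".tsv"), sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# FASTA / GTF / auxiliary tables


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into memory (uppercased) via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(genes: Sequence[GeneModel], path, source: str = "crispmeth") -> None:
    """Write gene models as GTF (1-based closed), one transcript per gene."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_expression_table(path) -> pd.DataFrame:
    """Read an expression table with columns gene_id, log2_fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "log2_fc", "fdr") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: expression table missing columns {missing}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise FormatError(f"{path}: FDR outside [0, 1]")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path} line {ln}: GMT needs name, desc, >=1 gene")
            sets[f[0]] = {g for g in f[2:] if g}
    return sets


def read_gene_list(path) -> set[str]:
    """Read one gene id per line, ignoring blanks and # comments."""
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        }
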