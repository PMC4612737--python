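"""Readers and writers for every on-disk representation the pipeline touches.

Coordinate convention
---------------------
All internal coordinates are 0-based, half-open ``[start, end)``, matching
native BED.  Any 1-based source (e.g. an array probe manifest exported from a
1-based annotation) must be converted at the reader boundary by the caller;
readers here never re-interpret coordinates.

Missing values are encoded as ``NA`` in all TSV dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "FragmentSet",
    "ProbeManifest",
    "BetaMatrix",
    "GeneModelSet",
    "IntervalSet",
    "ParseError",
    "ValidationError",
    "read_fragments",
    "write_fragments",
    "read_intervals",
    "write_intervals",
    "read_beta_matrix",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_gene_models",
    "write_gene_models",
    "read_genome",
    "write_genome",
    "read_call_matrix",
    "write_call_matrix",
    "write_beta_matrix",
]


class ParseError(ValueError):
    """A malformed record in an input file (reports the offending line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Declared genome: ordered sequence names and their lengths in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise ValidationError("genome must declare at least one sequence")
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValidationError(f"sequence {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass(frozen=True)
class FragmentSet:
    """Deduplicated mapped-fragment intervals for one sample.

    ``fragments`` has columns ``seq``, ``start``, ``end`` (0-based half-open),
    sorted by (seq, start, end), with exact duplicates collapsed — duplicate
    read pairs mapping to identical coordinates are treated as one fragment.
    """

    sample_id: str
    fragments: pd.DataFrame

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        records: Iterable[tuple[str, int, int]],
        genome: GenomeSpec | None = None,
    ) -> "FragmentSet":
        df = pd.DataFrame(records, columns=["seq", "start", "end"])
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValidationError(
                    f"fragment {bad.seq}:{bad.start}-{bad.end} has start >= end"
                )
            if genome is not None:
                unknown = set(df["seq"]) - set(genome.names)
                if unknown:
                    raise ValidationError(f"unknown sequence(s) {sorted(unknown)!r}")
                ends = df["seq"].map(dict(genome.lengths))
                if (df["end"] > ends).any():
                    raise ValidationError("fragment extends past declared sequence end")
        df = (
            df.drop_duplicates()
            .sort_values(["seq", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return cls(sample_id=sample_id, fragments=df)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class ProbeManifest:
    """Array probe annotation: one interrogated CpG per probe.

    ``table`` columns: ``probe_id`` (unique), ``seq``, ``pos`` (0-based bp of
    the CpG), ``assay_type`` (1 or 2, the two Infinium chemistries),
    ``strand`` (+/-).  An optional ``cpg_density`` column (local CpG count in
    the probe target region) is carried through when present; the capture
    platform's affinity depends on it.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "seq", "pos", "assay_type", "strand"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"manifest missing columns {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in manifest")
        if not set(t["assay_type"].unique()) <= {1, 2}:
            raise ValidationError("assay_type must be 1 or 2")

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x sample methylation degrees with per-cell detection P-values.

    ``beta`` holds values in [0, 1] (NaN = missing); ``detp`` is aligned
    cell-for-cell.  Rows are restricted to probes present in the manifest at
    read time — unannotated probes are dropped.
    """

    beta: pd.DataFrame
    detp: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detp.index) or not self.beta.columns.equals(
            self.detp.columns
        ):
            raise ValidationError("beta and detection-P grids are not aligned")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise ValidationError("beta values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape


@dataclass(frozen=True)
class GeneModelSet:
    """Transcript models: one ``transcript`` row plus ``exon`` rows per gene.

    Columns: ``gene_id``, ``seq``, ``strand``, ``tss``, ``start``, ``end``,
    ``feature`` in {transcript, exon}, ``pseudogene`` in {0, 1}.  The TSS is
    the transcript start on + and ``end - 1`` on -.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "seq", "strand", "tss", "start", "end", "feature", "pseudogene"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"gene model table missing columns {sorted(missing)}")
        tx = t[t["feature"] == "transcript"].set_index("gene_id")
        for _, row in t[t["feature"] == "exon"].iterrows():
            parent = tx.loc[row["gene_id"]]
            if row["start"] < parent["start"] or row["end"] > parent["end"]:
                raise ValidationError(
                    f"exon outside transcript interval for gene {row['gene_id']!r}"
                )
        plus = tx[tx["strand"] == "+"]
        minus = tx[tx["strand"] == "-"]
        if not (plus["tss"] == plus["start"]).all():
            raise ValidationError("TSS must equal transcript start on + strand")
        if not (minus["tss"] == minus["end"] - 1).all():
            raise ValidationError("TSS must equal transcript end-1 on - strand")

    @property
    def transcripts(self) -> pd.DataFrame:
        return self.table[self.table["feature"] == "transcript"]

    @property
    def exons(self) -> pd.DataFrame:
        return self.table[self.table["feature"] == "exon"]


@dataclass(frozen=True)
class IntervalSet:
    """Labeled genomic intervals (CpG islands, candidate DMRs, regions...).

    ``table`` columns: ``seq``, ``start``, ``end``, ``label`` (label may be
    empty).  Sorted per sequence; overlaps are allowed and preserved.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["seq", "start", "end", "label"])
    )

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise ValidationError(f"interval {bad.seq}:{bad.start}-{bad.end} has start >= end")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for rec in records:
            seq, start, end = rec[0], int(rec[1]), int(rec[2])
            label = rec[3] if len(rec) > 3 else ""
            rows.append((seq, start, end, label))
        df = pd.DataFrame(rows, columns=["seq", "start", "end", "label"])
        df = df.sort_values(["seq", "start", "end"], kind="mergesort").reset_index(drop=True)
        return cls(table=df)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _iter_bed_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_fragments(path: str | Path, genome: GenomeSpec) -> FragmentSet:
    """Read a BED3 fragment file for one sample; dedup and sort.

    Exact-duplicate intervals (PCR duplicates) collapse to a single fragment.
    The sample id is the file stem.
    """
    records = []
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    return FragmentSet.from_records(Path(path).stem, records, genome=genome)


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    frags.fragments.to_csv(path, sep="\t", header=False, index=False)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3/BED4 interval file (islands, cDMRs, regions)."""
    records = []
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start >= end")
        records.append((fields[0], start, end, fields[3] if len(fields) > 3 else ""))
    return IntervalSet.from_records(records)


def write_intervals(ivs: IntervalSet, path: str | Path) -> None:
    t = ivs.table
    cols = ["seq", "start", "end"] + (["label"] if t["label"].astype(str).str.len().any() else [])
    t[cols].to_csv(path, sep="\t", header=False, index=False)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric cell in column {col!r}") from exc
    return df


def read_beta_matrix(
    beta_path: str | Path, detp_path: str | Path, manifest: ProbeManifest
) -> BetaMatrix:
    """Read beta and detection-P TSVs, align by names, restrict to manifest.

    The two files must cover identical probe/sample sets; the detection-P
    grid is aligned to the beta grid by header names, so column order is
    irrelevant.  Probes absent from the manifest (no genomic annotation) are
    dropped.
    """
    beta = _read_tsv_matrix(beta_path)
    detp = _read_tsv_matrix(detp_path)
    if set(beta.index) != set(detp.index) or set(beta.columns) != set(detp.columns):
        raise ValidationError("beta and detection-P files cover different probes/samples")
    detp = detp.loc[beta.index, beta.columns]
    keep = beta.index.intersection(manifest.probe_ids)
    beta, detp = beta.loc[keep], detp.loc[keep]
    vals = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
            raise ValidationError("beta values outside [0, 1]")
    return BetaMatrix(beta=beta, detp=detp)


def write_beta_matrix(bm: BetaMatrix, beta_path: str | Path, detp_path: str | Path) -> None:
    bm.beta.to_csv(beta_path, sep="\t", na_rep="NA")
    bm.detp.to_csv(detp_path, sep="\t", na_rep="NA")


def read_probe_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "seq": str, "strand": str})
    return ProbeManifest(table=df)


def write_probe_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> GeneModelSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq": str, "strand": str})
    return GeneModelSet(table=df)


def write_gene_models(genes: GeneModelSet, path: str | Path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


def read_genome(path: str | Path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["seq", "length"])
    if df["seq"].duplicated().any():
        raise ValidationError("duplicate sequence names in genome file")
    return GenomeSpec(lengths=dict(zip(df["seq"], df["length"].astype(int))))


def write_genome(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    """Read a loci x samples binary call matrix (0/1/NA)."""
    df = _read_tsv_matrix(path)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0) | (vals == 1)
    if not ok.all():
        raise ValidationError("call matrix contains values other than 0/1/NA")
    return df


def write_call_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    # integers where present, NA elsewhere
    out = out.astype("Int64", errors="ignore")
    out.to_csv(path, sep="\t", na_rep="NA")
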