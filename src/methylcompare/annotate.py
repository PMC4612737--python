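"""Methylated-region calling and genomic-context annotation.

Regions: maximal stretches of the genome with positive fragment coverage,
separated by at least one uncovered base.  Context comes in two exact
partitions of the genome:

* CpG-island context — island / shore (within 2 kb of an island) / shelf
  (the next 2 kb) / open sea (everything else), with precedence
  island > shore > shelf.
* Functional context — promoter (1.5 kb upstream to 0.5 kb downstream of a
  TSS, strand-aware) / exon / intron / pseudogene / intergenic, with
  precedence promoter > exon > intron > pseudogene.

Both partitions cover every base exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FragmentSet, GeneModelSet, GenomeSpec, IntervalSet, ValidationError

__all__ = [
    "MethylatedRegionSet",
    "GenomePartition",
    "call_regions",
    "region_center",
    "build_island_context",
    "build_functional_partition",
    "annotate_position",
    "probe_region_ratio",
    "context_fractions",
    "compare_counts_paired",
]

ISLAND_LABELS = ("island", "shore", "shelf", "open_sea")
FUNCTIONAL_LABELS = ("promoter", "exon", "intron", "pseudogene", "intergenic")


# ---------------------------------------------------------------------------
# interval algebra on sorted, merged (start, end) arrays per sequence
# ---------------------------------------------------------------------------


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals; abutting intervals merge."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def _subtract(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """a \\ b for merged interval lists."""
    (as_, ae), (bs, be) = a, b
    out_s, out_e = [], []
    j = 0
    for s, e in zip(as_, ae):
        cur = s
        while j < len(bs) and be[j] <= cur:
            j += 1
        jj = j
        while jj < len(bs) and bs[jj] < e:
            if bs[jj] > cur:
                out_s.append(cur)
                out_e.append(bs[jj])
            cur = max(cur, be[jj])
            jj += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _expand(
    iv: tuple[np.ndarray, np.ndarray], pad: int, length: int
) -> tuple[np.ndarray, np.ndarray]:
    s = np.clip(iv[0] - pad, 0, length)
    e = np.clip(iv[1] + pad, 0, length)
    return _merge(s, e)


def _total(iv: tuple[np.ndarray, np.ndarray]) -> int:
    return int((iv[1] - iv[0]).sum())


@dataclass(frozen=True)
class MethylatedRegionSet:
    """Per-sample maximal positive-coverage intervals."""

    sample_id: str
    regions: pd.DataFrame  # seq, start, end

    def __len__(self) -> int:
        return len(self.regions)

    def to_interval_set(self) -> IntervalSet:
        return IntervalSet.from_records(
            list(self.regions[["seq", "start", "end"]].itertuples(index=False, name=None))
        )


def call_regions(frags: FragmentSet, genome: GenomeSpec) -> MethylatedRegionSet:
    """Maximal runs of bases covered by at least one fragment.

    Equivalent to merging overlapping fragment intervals; fragments abutting
    exactly ([a,b) then [b,c)) leave no uncovered base between them and
    therefore merge, while a single uncovered base splits regions.
    """
    rows = []
    for seq, sub in frags.fragments.groupby("seq", sort=True):
        s, e = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        for si, ei in zip(s, e):
            rows.append((seq, int(si), int(ei)))
    df = pd.DataFrame(rows, columns=["seq", "start", "end"])
    return MethylatedRegionSet(sample_id=frags.sample_id, regions=df)


def region_center(start: int, end: int) -> int:
    """Midpoint of the covered bases: floor((start + end - 1) / 2)."""
    if start >= end:
        raise ValidationError("empty region")
    return (start + end - 1) // 2


@dataclass(frozen=True)
class GenomePartition:
    """An exact labeling of every base: label -> per-seq merged intervals."""

    genome: GenomeSpec
    parts: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]

    def label_lengths(self) -> dict[str, int]:
        return {
            label: sum(_total(iv) for iv in per_seq.values())
            for label, per_seq in self.parts.items()
        }

    def lookup(self, seq: str, pos: int) -> str:
        return annotate_position(seq, pos, self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (label, seq, int(s), int(e))
            for label, per_seq in self.parts.items()
            for seq, (ss, ee) in per_seq.items()
            for s, e in zip(ss, ee)
        ]
        return pd.DataFrame(rows, columns=["label", "seq", "start", "end"]).sort_values(
            ["seq", "start"], kind="mergesort"
        ).reset_index(drop=True)


def _partition_from_layers(
    genome: GenomeSpec, layers: Sequence[tuple[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]], rest_label: str
) -> GenomePartition:
    """Flatten precedence-ordered layers into an exact partition."""
    parts: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
        label: {} for label, _ in layers
    }
    parts[rest_label] = {}
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    for seq, length in genome.lengths.items():
        claimed = empty
        for label, per_seq in layers:
            iv = per_seq.get(seq, empty)
            iv = _merge(iv[0].astype(np.int64), iv[1].astype(np.int64))
            own = _subtract(iv, claimed)
            parts[label][seq] = own
            claimed = _merge(
                np.concatenate([claimed[0], own[0]]), np.concatenate([claimed[1], own[1]])
            )
        whole = (np.array([0], dtype=np.int64), np.array([length], dtype=np.int64))
        parts[rest_label][seq] = _subtract(whole, claimed)
    return GenomePartition(genome=genome, parts=parts)


def _per_seq_intervals(df: pd.DataFrame, genome: GenomeSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for seq, sub in df.groupby("seq", sort=False):
        if seq not in genome:
            raise ValidationError(f"interval on unknown sequence {seq!r}")
        out[seq] = (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
    return out


def build_island_context(islands: IntervalSet, genome: GenomeSpec) -> GenomePartition:
    """Partition the genome into island / shore / shelf / open sea.

    Overlapping islands are merged first.  Shores are the 2 kb flanking each
    island end; shelves the next 2 kb; precedence island > shore > shelf
    resolves collisions between nearby islands.
    """
    raw = _per_seq_intervals(islands.table, genome)
    island_iv, shore_iv, shelf_iv = {}, {}, {}
    for seq, iv in raw.items():
        length = genome.lengths[seq]
        merged = _merge(*iv)
        island_iv[seq] = merged
        shore_iv[seq] = _expand(merged, 2_000, length)
        shelf_iv[seq] = _expand(merged, 4_000, length)
    return _partition_from_layers(
        genome,
        [("island", island_iv), ("shore", shore_iv), ("shelf", shelf_iv)],
        rest_label="open_sea",
    )


def build_functional_partition(genes: GeneModelSet, genome: GenomeSpec) -> GenomePartition:
    """Partition the genome into promoter/exon/intron/pseudogene/intergenic.

    Promoters span [TSS-1500, TSS+500) in transcript orientation, from
    non-pseudogene transcripts.  Exonic bases not claimed by a promoter are
    exon; remaining non-pseudogene transcript-body bases are intron.
    Pseudogene bodies keep whatever is not already claimed (they are
    truncated where they overlap real-gene features).
    """
    tx = genes.transcripts
    real_tx = tx[tx["pseudogene"] == 0]
    pseudo_tx = tx[tx["pseudogene"] == 1]
    prom_rows, body_rows = [], []
    for _, row in real_tx.iterrows():
        length = genome.lengths[row["seq"]]
        if row["strand"] == "+":
            ps, pe = row["tss"] - 1_500, row["tss"] + 500
        else:
            # mirror image: 1.5 kb upstream is to the right on the - strand
            ps, pe = row["tss"] - 500 + 1, row["tss"] + 1_500 + 1
        prom_rows.append((row["seq"], max(0, int(ps)), min(length, int(pe))))
        body_rows.append((row["seq"], int(row["start"]), int(row["end"])))
    exon_rows = [
        (r["seq"], int(r["start"]), int(r["end"]))
        for _, r in genes.exons.iterrows()
        if r["gene_id"] in set(real_tx["gene_id"])
    ]
    pseudo_rows = [
        (r["seq"], int(r["start"]), int(r["end"])) for _, r in pseudo_tx.iterrows()
    ]

    def as_map(rows):
        if not rows:
            return {}
        df = pd.DataFrame(rows, columns=["seq", "start", "end"])
        df = df[df["start"] < df["end"]]
        return _per_seq_intervals(df, genome)

    return _partition_from_layers(
        genome,
        [
            ("promoter", as_map(prom_rows)),
            ("exon", as_map(exon_rows)),
            ("intron", as_map(body_rows)),
            ("pseudogene", as_map(pseudo_rows)),
        ],
        rest_label="intergenic",
    )


def annotate_position(seq: str, pos: int, partition: GenomePartition) -> str:
    """The unique partition label at a genomic position."""
    if seq not in partition.genome or not 0 <= pos < partition.genome.lengths[seq]:
        raise ValidationError(f"position {seq}:{pos} outside genome")
    for label, per_seq in partition.parts.items():
        iv = per_seq.get(seq)
        if iv is None or len(iv[0]) == 0:
            continue
        i = np.searchsorted(iv[0], pos, side="right") - 1
        if i >= 0 and pos < iv[1][i]:
            return label
    raise AssertionError("partition does not cover position")  # pragma: no cover


def probe_region_ratio(probe_cov: np.ndarray, regions: MethylatedRegionSet) -> float:
    """(# probe loci with non-zero coverage) / (# methylated regions).

    The headline genome-wide comparison statistic: how much of what the
    capture platform sees is also interrogated by the array.  Using a ratio
    implicitly adjusts for sequencing depth.
    """
    if len(regions) == 0:
        raise ValidationError("no methylated regions: ratio undefined")
    return float((np.asarray(probe_cov) >= 1).sum() / len(regions))


def context_fractions(
    labels: Sequence[str], reference: Mapping[str, float]
) -> tuple[pd.Series, float, float]:
    """Per-label fractions plus a chi-square test against reference fractions.

    ``reference`` gives the expected label distribution (e.g. the
    genome-wide base composition); returns (fractions, chi2, P).
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("no labels to summarize")
    counts = pd.Series(labels).value_counts()
    cats = list(reference)
    unknown = set(counts.index) - set(cats)
    if unknown:
        raise ValidationError(f"labels {sorted(unknown)} absent from reference")
    obs = np.array([counts.get(c, 0) for c in cats], dtype=float)
    ref = np.array([reference[c] for c in cats], dtype=float)
    if (ref <= 0).any():
        raise ValidationError("reference proportions must be positive")
    ref = ref / ref.sum()
    chi2, p = stats.chisquare(obs, f_exp=obs.sum() * ref)
    fractions = pd.Series(obs / obs.sum(), index=cats)
    return fractions, float(chi2), float(p)


def compare_counts_paired(
    counts_a: Sequence[float], counts_b: Sequence[float], method: str = "wilcoxon"
) -> tuple[float, float]:
    """Paired comparison of per-sample counts between the two platforms.

    Default is the Wilcoxon signed-rank test on per-sample differences
    (two-sided); ``method="kruskal"`` runs an unpaired Kruskal-Wallis
    instead for users who want the rank-sum alternative.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired count vectors differ in length")
    if len(a) < 2:
        raise ValidationError("need at least two pairs")
    if method == "kruskal":
        stat, p = stats.kruskal(a, b)
    else:
        if np.all(a == b):
            raise ValidationError("all paired differences are zero")
        stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    return float(stat), float(p)
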