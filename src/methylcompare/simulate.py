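"""Synthetic study generator with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: a latent binary methylation status per locus and sample, from which
both platforms' observables are derived —

* paired binary calls from the seven-parameter latent-class model
  (conditional sensitivities/specificities with within-class covariances),
* array beta-values from a two-component Beta mixture (the type-2 chemistry
  compresses both components toward 0.5, mimicking its narrower
  distribution) plus detection P-values with ~0.1% failures,
* capture fragments with Poisson counts whose rate saturates in local CpG
  density (the capture platform's affinity bias) plus a small nonspecific
  rate at unmethylated loci.

Default parameter values place the simulated cohort in the regime the
estimation stages are designed for: 70 samples (5 controls, 65 tumours),
prevalence ~0.52, array sensitivity/specificity ~0.74/0.87 and capture
~0.52/0.94 — a mid-threshold type-1-chemistry operating point.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    FragmentSet,
    GeneModelSet,
    GenomeSpec,
    IntervalSet,
    ProbeManifest,
    ValidationError,
)
from .latent import LatentClassParams, class_cell_probs

__all__ = [
    "TruthConfig",
    "AssayModel",
    "generate_latent",
    "generate_paired_calls",
    "generate_beta",
    "generate_fragments",
    "generate_probe_manifest",
    "generate_background_sites",
    "generate_genome_fixture",
]


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth layout of the simulated cohort.

    ``group_labels`` is a 0/1 vector per sample (0 = control, 1 = case);
    ``differential_loci`` maps locus index -> prevalence shift delta applied
    in the case group (clamped so pi + delta stays in [0, 1]).
    """

    n_loci: int
    n_samples: int = 70
    pi: float = 0.515
    group_labels: tuple[int, ...] | None = None
    differential_loci: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_samples < 1:
            raise ValidationError("n_loci and n_samples must be >= 1")
        if not 0.0 < self.pi < 1.0 and self.pi not in (0.0, 1.0):
            raise ValidationError("pi must be in [0, 1]")
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValidationError("one group label per sample required")
        if any(l < 0 or l >= self.n_loci for l in self.differential_loci):
            raise ValidationError("differential locus index out of range")

    @property
    def groups(self) -> np.ndarray:
        if self.group_labels is not None:
            return np.asarray(self.group_labels, dtype=int)
        # study-shaped default: 5 controls then cases
        n_controls = min(5, self.n_samples - 1) if self.n_samples > 1 else 0
        return np.array([0] * n_controls + [1] * (self.n_samples - n_controls))


@dataclass(frozen=True)
class AssayModel:
    """Observation model linking latent status to both platforms' signals.

    ``params`` carries the latent-class operating point (test 1 = array,
    test 2 = capture).  Beta-mixture shapes are per latent state; the type-2
    chemistry shrinks draws toward 0.5 by ``type2_compression``.  Fragment
    counts are Poisson with rate ``depth * density/(density + density_halfsat)``
    at methylated loci and ``depth * epsilon`` (nonspecific capture) at
    unmethylated ones.
    """

    params: LatentClassParams = field(
        default_factory=lambda: LatentClassParams(
            se1=0.743, se2=0.525, sp1=0.868, sp2=0.938, pi=0.515, covp=0.02, covn=0.005
        )
    )
    beta_meth_shape: tuple[float, float] = (1.2, 1.0)
    beta_unmeth_shape: tuple[float, float] = (1.1, 6.0)
    type2_compression: float = 0.3
    detection_fail_rate: float = 0.001
    detection_alpha: float = 0.05
    depth: float = 3.5
    epsilon: float = 0.02
    density_halfsat: float = 24.0
    fragment_length: int = 200

    def density_weight(self, density: np.ndarray) -> np.ndarray:
        d = np.asarray(density, dtype=float)
        return d / (d + self.density_halfsat)


def generate_latent(config: TruthConfig) -> np.ndarray:
    """Latent methylation status D (loci x samples), Bernoulli per cell.

    Cell probability is pi, shifted by delta in the case group at
    differential loci, clamped to [0, 1].  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    prob = np.full((config.n_loci, config.n_samples), config.pi)
    groups = config.groups
    for locus, delta in config.differential_loci.items():
        prob[locus] = np.clip(config.pi + delta * groups, 0.0, 1.0)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def generate_paired_calls(
    latent: np.ndarray, params: LatentClassParams, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired binary calls with the model's within-class joint distribution.

    Per cell the joint outcome (test1, test2) is drawn from the four-cell
    conditional distribution of the latent class, so the conditional
    marginals are exactly Se/1-Sp and the within-class covariances are the
    model's covp/covn.
    """
    rng = np.random.default_rng(seed)
    meth, unmeth = class_cell_probs(params)
    u = rng.random(latent.shape)
    cum_m = np.cumsum(meth)
    cum_u = np.cumsum(unmeth)
    cell = np.where(
        latent == 1,
        np.searchsorted(cum_m, np.minimum(u, cum_m[-1] - 1e-15), side="right"),
        np.searchsorted(cum_u, np.minimum(u, cum_u[-1] - 1e-15), side="right"),
    )
    # cells: 0=++, 1=+-, 2=-+, 3=--
    calls1 = np.isin(cell, (0, 1)).astype(float)
    calls2 = np.isin(cell, (0, 2)).astype(float)
    return calls1, calls2


def generate_beta(
    latent: np.ndarray, manifest: ProbeManifest, model: AssayModel, seed: int = 0
) -> BetaMatrix:
    """Array beta-values and detection P-values given latent status.

    Beta is drawn from the methylated or unmethylated Beta component; type-2
    probes' draws are compressed toward 0.5.  Detection P-values are uniform
    on [0, alpha) except for a ``detection_fail_rate`` fraction uniform on
    [alpha, 1).
    """
    if len(manifest) != latent.shape[0]:
        raise ValidationError("one manifest row per locus required")
    rng = np.random.default_rng(seed)
    a_m, b_m = model.beta_meth_shape
    a_u, b_u = model.beta_unmeth_shape
    meth_draw = rng.beta(a_m, b_m, size=latent.shape)
    unmeth_draw = rng.beta(a_u, b_u, size=latent.shape)
    beta = np.where(latent == 1, meth_draw, unmeth_draw)
    is_type2 = (manifest.table["assay_type"].to_numpy() == 2)[:, None]
    compressed = 0.5 + (1.0 - model.type2_compression) * (beta - 0.5)
    beta = np.where(is_type2, compressed, beta)
    fails = rng.random(latent.shape) < model.detection_fail_rate
    u = rng.random(latent.shape)
    detp = np.where(
        fails,
        model.detection_alpha + u * (1.0 - model.detection_alpha),
        u * model.detection_alpha,
    )
    samples = [f"S{i + 1:02d}" for i in range(latent.shape[1])]
    idx = manifest.probe_ids
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=samples),
        detp=pd.DataFrame(detp, index=idx, columns=samples),
    )


def generate_fragments(
    latent: np.ndarray,
    loci: ProbeManifest,
    model: AssayModel,
    genome: GenomeSpec,
    depth: float | np.ndarray | None = None,
    seed: int = 0,
) -> list[FragmentSet]:
    """Capture fragments per sample: Poisson counts around each locus.

    The per-locus rate is ``depth * w(cpg_density)`` when methylated and
    ``depth * epsilon`` when not; fragments are ~``fragment_length`` bp,
    jittered around the CpG so deduplication rarely collapses them.
    """
    if len(loci) != latent.shape[0]:
        raise ValidationError("one manifest row per locus required")
    n_samples = latent.shape[1]
    depth_vec = np.full(n_samples, model.depth if depth is None else depth, dtype=float)
    if np.ndim(depth) == 1:
        depth_vec = np.asarray(depth, dtype=float)
    if (depth_vec < 0).any():
        raise ValidationError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    dens = loci.table.get("cpg_density")
    density = (
        dens.to_numpy(dtype=float) if dens is not None else np.full(len(loci), 7.0)
    )
    w = model.density_weight(density)
    pos = loci.table["pos"].to_numpy()
    seqs = loci.table["seq"].to_numpy()
    seq_len = dict(genome.lengths)
    out = []
    for s in range(n_samples):
        rate = depth_vec[s] * np.where(latent[:, s] == 1, w, model.epsilon)
        counts = rng.poisson(rate)
        records = []
        for locus in np.nonzero(counts)[0]:
            for _ in range(counts[locus]):
                length = model.fragment_length + int(rng.integers(-20, 21))
                center = pos[locus] + int(rng.integers(-80, 81))
                start = max(0, center - length // 2)
                end = min(seq_len[seqs[locus]], start + length)
                if start < end:
                    records.append((seqs[locus], start, end))
        out.append(FragmentSet.from_records(f"S{s + 1:02d}", records, genome=genome))
    return out


def generate_probe_manifest(
    genome: GenomeSpec,
    n_loci: int,
    seed: int = 0,
    frac_type2: float = 0.6,
    id_prefix: str = "cg",
) -> ProbeManifest:
    """Random probe manifest: positions uniform over the genome, local CpG
    densities higher for type-1 probes (medians ~7 vs ~4), alternating
    strands.

    With ``id_prefix`` this also serves to lay out background CpG sites
    that no array probe interrogates but the capture platform can still
    see — the capture assay is genome-wide, so its methylated regions are
    not confined to assayed loci.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.names)
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    seq_idx = rng.choice(len(names), size=n_loci, p=lengths / lengths.sum())
    pos = (rng.random(n_loci) * (lengths[seq_idx] - 200) + 100).astype(np.int64)
    assay = np.where(rng.random(n_loci) < frac_type2, 2, 1)
    density = np.where(
        assay == 1, rng.poisson(6.0, n_loci) + 1, rng.poisson(3.0, n_loci) + 1
    )
    df = pd.DataFrame(
        {
            "probe_id": [f"{id_prefix}{i:08d}" for i in range(n_loci)],
            "seq": [names[i] for i in seq_idx],
            "pos": pos,
            "assay_type": assay,
            "strand": np.where(rng.random(n_loci) < 0.5, "+", "-"),
            "cpg_density": density,
        }
    )
    df = df.sort_values(["seq", "pos"], kind="mergesort").reset_index(drop=True)
    df["probe_id"] = [f"{id_prefix}{i:08d}" for i in range(n_loci)]
    return ProbeManifest(table=df)


def generate_background_sites(
    genome: GenomeSpec,
    n_sites: int,
    probes: ProbeManifest,
    seed: int = 0,
    min_distance: int = 500,
) -> ProbeManifest:
    """CpG sites the capture platform can see but no array probe assays.

    On a real genome, assayed probes are kilobases apart, so fragments
    captured at non-assayed sites essentially never overlap a probe
    position; the compact fixture genome is ~50x denser in probes, so that
    separation is enforced explicitly by keeping background sites at least
    ``min_distance`` bp away from every probe.
    """
    candidates = generate_probe_manifest(
        genome, 2 * n_sites + 100, seed=seed, frac_type2=0.0, id_prefix="bg"
    )
    keep = np.ones(len(candidates), dtype=bool)
    probe_pos = {
        seq: np.sort(sub["pos"].to_numpy())
        for seq, sub in probes.table.groupby("seq", sort=False)
    }
    for i, row in enumerate(candidates.table.itertuples()):
        pos = probe_pos.get(row.seq)
        if pos is None or len(pos) == 0:
            continue
        j = np.searchsorted(pos, row.pos)
        near = []
        if j > 0:
            near.append(abs(row.pos - pos[j - 1]))
        if j < len(pos):
            near.append(abs(pos[j] - row.pos))
        if near and min(near) < min_distance:
            keep[i] = False
    table = candidates.table[keep].head(n_sites).reset_index(drop=True)
    table = table.assign(probe_id=[f"bg{i:08d}" for i in range(len(table))])
    return ProbeManifest(table=table)


def generate_genome_fixture(
    seed: int = 0,
) -> tuple[GenomeSpec, IntervalSet, GeneModelSet, IntervalSet]:
    """Small declared genome with islands, gene models and candidate DMRs.

    Two sequences of 1 Mb.  Islands are spaced > 8 kb apart so the default
    fixture's shores and shelves never collide; genes lie on both strands
    with multiple exons, a ~10% pseudogene fraction, and cDMR intervals are
    scattered independently.
    """
    rng = np.random.default_rng(seed)
    genome = GenomeSpec(lengths={"chr1": 1_000_000, "chr2": 1_000_000})

    island_rows = []
    for seq in genome.names:
        cursor = 12_000
        while cursor < genome.lengths[seq] - 20_000:
            width = int(rng.integers(400, 2_000))
            island_rows.append((seq, cursor, cursor + width, "CpG"))
            cursor += width + 8_001 + int(rng.integers(0, 20_000))
    islands = IntervalSet.from_records(island_rows)

    gene_rows = []
    gid = 0
    for seq in genome.names:
        cursor = 5_000
        while cursor < genome.lengths[seq] - 40_000:
            body = int(rng.integers(5_000, 20_000))
            start, end = cursor, cursor + body
            strand = "+" if rng.random() < 0.5 else "-"
            pseudo = int(rng.random() < 0.1)
            tss = start if strand == "+" else end - 1
            gene_id = f"G{gid:04d}"
            gene_rows.append((gene_id, seq, strand, tss, start, end, "transcript", pseudo))
            if not pseudo:
                n_exons = int(rng.integers(2, 5))
                bounds = np.sort(rng.integers(start, end, size=2 * n_exons))
                for k in range(n_exons):
                    es, ee = int(bounds[2 * k]), int(bounds[2 * k + 1])
                    if es < ee:
                        gene_rows.append((gene_id, seq, strand, tss, es, ee, "exon", 0))
            gid += 1
            cursor = end + 3_000 + int(rng.integers(0, 15_000))
    genes = GeneModelSet(
        table=pd.DataFrame(
            gene_rows,
            columns=[
                "gene_id",
                "seq",
                "strand",
                "tss",
                "start",
                "end",
                "feature",
                "pseudogene",
            ],
        )
    )

    cdmr_rows = []
    for seq in genome.names:
        starts = np.sort(rng.choice(genome.lengths[seq] - 4_000, size=100, replace=False))
        for s in starts:
            cdmr_rows.append((seq, int(s), int(s) + int(rng.integers(500, 3_000)), "cDMR"))
    cdmrs = IntervalSet.from_records(cdmr_rows)
    return genome, islands, genes, cdmrs
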