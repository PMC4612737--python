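"""End-to-end orchestration: simulate or load a cohort, dichotomize both
platforms, estimate per-sample conditional accuracy by latent-class MCMC,
and run the comparison stages (annotation, concordance, differential
testing, ordination).

The per-sample summary aggregates posterior medians over converged models
only, per assay type and beta threshold, reporting mean, SD, min and max —
the shape of a platform-comparison summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotate as ann
from . import calls as calls_mod
from . import io as mio
from . import ordination as ord_mod
from .dmr import fisher_tests, filter_constant_loci, permutation_fdr, permutation_null
from .latent import MCMCConfig, PosteriorSummary, estimate_sample
from .simulate import (
    AssayModel,
    TruthConfig,
    generate_background_sites,
    generate_beta,
    generate_fragments,
    generate_genome_fixture,
    generate_latent,
    generate_probe_manifest,
)

logger = logging.getLogger("methylcompare")

__all__ = ["RunConfig", "run_pipeline", "summarize_cohort", "paired_stat_comparison"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults mirror the analysis profile.

    The 0.1 beta threshold is excluded from the default grid (too low to
    define methylation status reliably) but may be supplied explicitly.
    """

    thresholds: tuple[float, ...] = (0.2, 0.3, 0.4)
    detection_alpha: float = 0.05
    min_fragments: int = 2_000_000
    q: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    n_loci: int = 5_000
    n_samples: int = 12
    frac_differential: float = 0.05
    delta: float = 0.45
    # background methylatable CpG sites per assayed probe: the capture
    # platform is genome-wide, so most of its regions fall outside probes
    background_factor: int = 3
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(n_chains=4, n_iter=4_000))

    def __post_init__(self) -> None:
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise mio.ValidationError("thresholds must lie in (0, 1)")
        if list(self.thresholds) != sorted(self.thresholds):
            raise mio.ValidationError("thresholds must be sorted")


def summarize_cohort(
    summaries: dict[str, PosteriorSummary],
) -> pd.DataFrame:
    """Aggregate per-sample posterior medians over converged models.

    Returns rows (statistic, mean, sd, min, max, n_samples) for prevalence
    and each test's sensitivity/specificity.
    """
    stats_map = {
        "prevalence": "pi",
        "sens_test1": "se1",
        "spec_test1": "sp1",
        "sens_test2": "se2",
        "spec_test2": "sp2",
    }
    converged = {s: ps for s, ps in summaries.items() if ps.converged}
    rows = []
    for label, param in stats_map.items():
        vals = np.array([ps.median[param] for ps in converged.values()])
        if len(vals):
            rows.append(
                (label, vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0,
                 vals.min(), vals.max(), len(vals))
            )
        else:
            rows.append((label, np.nan, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["statistic", "mean", "sd", "min", "max", "n_samples"]
    )


def paired_stat_comparison(
    per_sample_a: Sequence[float], per_sample_b: Sequence[float]
) -> tuple[float, float]:
    """Paired t-test (two-sided) on per-sample statistic differences."""
    from scipy import stats

    a = np.asarray(per_sample_a, dtype=float)
    b = np.asarray(per_sample_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise mio.ValidationError("need >= 2 paired values")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise mio.ValidationError("zero-variance differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic comparison end-to-end.

    Generates a cohort (genome fixture, manifest, latent truth, betas,
    fragments), dichotomizes both platforms at each threshold, estimates
    per-sample latent-class parameters per assay type, and runs the
    annotation, concordance, differential and ordination stages.  Every
    intermediate is written under ``out_dir`` when given.  Fully
    deterministic given the config.
    """
    rng_seed = config.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("generating genome fixture and cohort (seed=%d)", rng_seed)
    genome, islands, genes, cdmrs = generate_genome_fixture(seed=rng_seed)
    manifest = generate_probe_manifest(genome, config.n_loci, seed=rng_seed + 1)
    n_diff = int(config.frac_differential * config.n_loci)
    truth_cfg = TruthConfig(
        n_loci=config.n_loci,
        n_samples=config.n_samples,
        differential_loci={i: config.delta for i in range(n_diff)},
        seed=rng_seed + 2,
    )
    model = AssayModel()
    latent = generate_latent(truth_cfg)
    beta = generate_beta(latent, manifest, model, seed=rng_seed + 3)
    # capture fragments arise from assayed probes plus background CpG sites
    bg_manifest = generate_background_sites(
        genome, config.background_factor * config.n_loci, manifest, seed=rng_seed + 7
    )
    bg_latent = generate_latent(
        TruthConfig(
            n_loci=len(bg_manifest), n_samples=config.n_samples, seed=rng_seed + 8
        )
    )
    combined = mio.ProbeManifest(
        table=pd.concat([manifest.table, bg_manifest.table], ignore_index=True)
    )
    frags = generate_fragments(
        np.vstack([latent, bg_latent]), combined, model, genome, seed=rng_seed + 4
    )
    groups = truth_cfg.groups

    # capture calls (shared across thresholds)
    cov = np.stack([calls_mod.coverage_at_loci(f, manifest) for f in frags], axis=1)
    mcap_calls = pd.DataFrame(
        (cov >= 1).astype(float), index=manifest.probe_ids, columns=beta.beta.columns
    )
    assay_type = manifest.table.set_index("probe_id")["assay_type"]

    # latent-class estimation per sample x threshold x assay type
    logger.info("estimating latent-class models")
    estimates: dict[tuple[float, int], dict[str, PosteriorSummary]] = {}
    summary_frames = []
    for threshold in config.thresholds:
        array_calls = calls_mod.call_from_beta(beta, threshold, config.detection_alpha)
        for atype in (1, 2):
            probes = assay_type.index[assay_type == atype]
            per_sample = {}
            for k, sample in enumerate(array_calls.columns):
                mcmc_cfg = MCMCConfig(
                    n_chains=config.mcmc.n_chains,
                    n_iter=config.mcmc.n_iter,
                    seed=(rng_seed * 1_000 + int(threshold * 10) * 100 + atype * 50 + k)
                    % (2**31),
                    rhat_threshold=config.mcmc.rhat_threshold,
                    thin=config.mcmc.thin,
                )
                per_sample[sample] = estimate_sample(
                    array_calls.loc[probes, sample],
                    mcap_calls.loc[probes, sample],
                    mcmc_cfg,
                )
            estimates[(threshold, atype)] = per_sample
            frame = summarize_cohort(per_sample)
            frame.insert(0, "assay_type", atype)
            frame.insert(0, "threshold", threshold)
            summary_frames.append(frame)
    summary = pd.concat(summary_frames, ignore_index=True)

    # annotation of methylated regions for the first sample
    logger.info("annotating regions and contexts")
    island_part = ann.build_island_context(islands, genome)
    func_part = ann.build_functional_partition(genes, genome)
    regions0 = ann.call_regions(frags[0], genome)
    centers = [
        (r.seq, ann.region_center(r.start, r.end))
        for r in regions0.regions.itertuples()
    ]
    region_labels = [ann.annotate_position(seq, pos, island_part) for seq, pos in centers]
    ratio = (
        ann.probe_region_ratio(cov[:, 0], regions0) if len(regions0) else np.nan
    )

    # differential testing at the selected threshold (0.3 when present)
    sel = 0.3 if 0.3 in config.thresholds else config.thresholds[0]
    array_calls = calls_mod.call_from_beta(beta, sel, config.detection_alpha)
    retained = filter_constant_loci(array_calls)
    observed = fisher_tests(array_calls.loc[retained], groups)
    null = permutation_null(array_calls.loc[retained], groups, seed=rng_seed + 5)
    dmr_table = permutation_fdr(observed, null, q=config.q)

    # ordination on the capture calls
    logger.info("ordination and global test")
    dist = ord_mod.jaccard_distances(mcap_calls)
    pco_res = ord_mod.pco(dist)
    stat, pval = ord_mod.between_group_test(
        pco_res, groups, n_perm=config.n_perm, seed=rng_seed + 6
    )

    results = {
        "summary": summary,
        "estimates": estimates,
        "dmr": dmr_table,
        "ordination": {"statistic": stat, "p": pval, "pco": pco_res},
        "regions_sample1": regions0,
        "region_island_labels": region_labels,
        "probe_region_ratio": ratio,
        "genome": genome,
        "manifest": manifest,
        "latent": latent,
        "beta": beta,
        "mcap_calls": mcap_calls,
        "groups": groups,
    }

    if out is not None:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        dmr_table.table.to_csv(out / "dmr.tsv", sep="\t", index=False)
        pco_res.coordinates.to_csv(out / "pco_coordinates.tsv", sep="\t")
        pd.DataFrame({"eigenvalue": pco_res.eigenvalues}).to_csv(
            out / "pco_eigenvalues.tsv", sep="\t", index=False
        )
        with open(out / "global_test.tsv", "w") as fh:
            fh.write(f"statistic\tp\n{stat:.6g}\t{pval:.6g}\n")
        regions0.regions.to_csv(out / "regions_sample1.bed", sep="\t", header=False, index=False)
        mio.write_call_matrix(mcap_calls, out / "mcap_calls.tsv")
        logger.info("artifacts written to %s", out)
    return results
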