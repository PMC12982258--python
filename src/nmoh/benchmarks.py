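"""Calibration and recovery benchmarks exercising the whole toolkit.

These routines measure the package against known ground truth: Gaussian
tail-probability calibration of the segmentation threshold on pure-noise
phantoms, recovery of exact blob volumes, a hand-crafted truth table for the
orthostatic classifier, enumeration and algebraic oracles for the rank
tests, type-I error calibration under simulated nulls, and recovery of the
designed qualitative pattern (an LC effect confined to PD without OH, no
SNc effect, volume-fall coupling confined to (+)OH) at study-scale subgroup
sizes.  Every routine is deterministic under its seed argument.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

from .autonomic import label_subject
from .vignettes import VIGNETTES
from .cohort import generate_cohort, headline_cohort_spec
from .phantom import BlobSpec, PhantomSpec, generate_phantom
from .pipeline import (
    PipelineConfig,
    ensure_labels,
    run_correlation_battery,
    run_subgroup_comparisons,
)
from .segmentation import ThresholdConfig, average_measurements, segment_target
from .stats import kruskal_wallis, mann_whitney_u, quade_ancova, spearman

__all__ = [
    "false_positive_calibration",
    "phantom_volume_recovery",
    "classifier_truth_table",
    "mann_whitney_enumeration_check",
    "rank_test_identities",
    "type_one_error_calibration",
    "headline_pattern_recovery",
]


# ---------------------------------------------------------------------------
# Segmentation calibration


def _noise_phantom_spec(seed: int) -> PhantomSpec:
    # large reference boxes keep threshold-estimation jitter far below the
    # binomial noise of the 10,000-voxel target box
    return PhantomSpec(
        grid_shape=(96, 80, 12),
        reference_boxes=(((0, 32), (0, 80), (0, 12)), ((32, 64), (0, 80), (0, 12))),
        mask_boxes={
            "LC": ((64, 89), (0, 50), (0, 8)),
            "SNc": ((64, 89), (0, 50), (0, 8)),
        },
        seed=seed,
    )


def false_positive_calibration(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Suprathreshold fraction on pure noise vs the Gaussian tail 1 - Phi(k).

    Each seed renders a no-blob phantom with a 10,000-voxel target mask; the
    LC (k = 2.88) and SNc (k = 2.57) rules are applied and suprathreshold
    voxels pooled over seeds.  Returns observed counts/fractions alongside
    the theoretical tail probabilities.
    """
    cfg = ThresholdConfig()
    counts = {"LC": 0, "SNc": 0}
    mask_voxels = None
    for i in range(n_seeds):
        image, rois, _ = generate_phantom(_noise_phantom_spec(base_seed + i))
        avg = average_measurements(image)
        for target in ("LC", "SNc"):
            res = segment_target(avg, rois, cfg, target)
            counts[target] += res.voxel_count
        if mask_voxels is None:
            mask_voxels = int((rois.lc_mask >= cfg.mask_binarize_p).sum())
    n_total = n_seeds * mask_voxels
    return {
        target: {
            "count": counts[target],
            "n": n_total,
            "fraction": counts[target] / n_total,
            "expected_p": float(norm_dist.sf(cfg.k_for(target))),
        }
        for target in ("LC", "SNc")
    }


def phantom_volume_recovery(
    n_phantoms: int = 100, base_seed: int = 0, contrast: float = 6.0
) -> dict:
    """Recovery of a 12-voxel LC blob at the given contrast (in SD units).

    Returns the mean absolute voxel-count error over phantoms and the
    largest deviation of volume_mm3 from voxel_count x 0.4563.
    """
    errors = []
    identity_dev = 0.0
    for i in range(n_phantoms):
        spec = PhantomSpec(
            grid_shape=(40, 40, 10),
            reference_boxes=(((0, 8), (0, 40), (0, 10)), ((8, 16), (0, 40), (0, 10))),
            blobs=[BlobSpec("LC", (27.5, 20.5, 5.0), (1.0, 1.0, 2.0), contrast)],
            seed=base_seed + i,
        )
        image, rois, truth = generate_phantom(spec)
        res = segment_target(average_measurements(image), rois, ThresholdConfig(), "LC")
        errors.append(abs(res.voxel_count - truth.voxel_counts["LC"]))
        identity_dev = max(
            identity_dev, abs(res.volume_mm3 - res.voxel_count * 0.4563)
        )
    return {
        "mean_abs_voxel_error": float(np.mean(errors)),
        "max_volume_identity_dev": identity_dev,
        "true_voxel_count": 12,
        "n": n_phantoms,
    }


# ---------------------------------------------------------------------------
# Classifier truth table


def classifier_truth_table() -> dict:
    """Run the hand-crafted vitals vignettes through the classifier.

    Returns per-vignette expected/observed labels and the overall accuracy
    (fraction of vignettes on which every expected field matches).
    """
    rows = []
    n_correct = 0
    for name, panel, expected in VIGNETTES:
        label = label_subject(panel)
        observed = {key: getattr(label, key) for key in expected}
        ok = all(
            (observed[k] == v)
            or (isinstance(v, float) and observed[k] is not None
                and abs(observed[k] - v) < 1e-9)
            for k, v in expected.items()
        )
        n_correct += ok
        rows.append({"vignette": name, "expected": expected, "observed": observed, "ok": ok})
    return {"rows": rows, "accuracy": n_correct / len(rows), "n": len(rows)}


# ---------------------------------------------------------------------------
# Statistical oracles


def _brute_force_mw_distribution(n1: int, n2: int) -> dict[float, int]:
    """Null counts of U1 by full enumeration of rank assignments."""
    dist: dict[float, int] = {}
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        dist[u] = dist.get(u, 0) + 1
    return dist


def mann_whitney_enumeration_check(max_n: int = 6) -> dict:
    """Exact Mann-Whitney p vs brute-force enumeration, all tie-free inputs.

    A tie-free sample's p depends only on which ranks land in x, so checking
    every rank assignment for every n1, n2 <= max_n covers all tie-free
    inputs of those sizes.  The oracle counts arrangements at least as
    extreme in both tails of the fully enumerated U distribution.  Returns
    the largest absolute discrepancy.
    """
    worst = 0.0
    n_checked = 0
    for n1 in range(1, max_n + 1):
        for n2 in range(n1, max_n + 1):
            dist = _brute_force_mw_distribution(n1, n2)
            total = sum(dist.values())
            positions = list(range(1, n1 + n2 + 1))
            for combo in itertools.combinations(positions, n1):
                x = [float(c) for c in combo]
                y = [float(p) for p in positions if p not in combo]
                res = mann_whitney_u(x, y, mode="exact")
                u_min = res.statistic
                hi = n1 * n2 - u_min
                as_extreme = sum(c for u, c in dist.items() if u <= u_min or u >= hi)
                p_bf = min(1.0, as_extreme / total)
                worst = max(worst, abs(res.p_raw - p_bf))
                n_checked += 1
    return {"max_abs_error": worst, "n": n_checked}


def rank_test_identities(seed: int = 0) -> dict:
    """Algebraic identities tying the rank tests together.

    * worked Kruskal-Wallis H on {1,2},{3,4},{5,6};
    * two-group tie-free H equals the squared untied Mann-Whitney deviate;
    * Quade with no covariates equals one-way ANOVA on ranks.
    """
    rng = np.random.default_rng(seed)
    worked_h = kruskal_wallis([[1, 2], [3, 4], [5, 6]]).statistic

    h_z2_dev = 0.0
    for _ in range(20):
        n1, n2 = rng.integers(4, 12), rng.integers(4, 12)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        h = kruskal_wallis([x, y]).statistic
        u1 = rankdata(np.concatenate([x, y]))[:n1].sum() - n1 * (n1 + 1) / 2
        z = (u1 - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        h_z2_dev = max(h_z2_dev, abs(h - z**2))

    quade_dev = 0.0
    for _ in range(20):
        y = rng.normal(size=30)
        g = rng.integers(0, 3, size=30)
        if len(set(g)) < 3:
            continue
        f_quade = quade_ancova(y, g, []).statistic
        # independent route: classic one-way ANOVA computed on the ranks
        r = rankdata(y)
        grand = r.mean()
        ssb = sum((r[g == k]).size * ((r[g == k]).mean() - grand) ** 2 for k in set(g))
        ssw = sum(((r[g == k] - (r[g == k]).mean()) ** 2).sum() for k in set(g))
        f_ref = (ssb / (len(set(g)) - 1)) / (ssw / (30 - len(set(g))))
        quade_dev = max(quade_dev, abs(f_quade - f_ref))

    return {
        "kruskal_worked_h": float(worked_h),
        "h_z2_max_dev": float(h_z2_dev),
        "quade_rank_anova_max_dev": float(quade_dev),
    }


def type_one_error_calibration(
    n_reps: int = 2000, n: int = 60, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Null rejection rates for the battery's workhorse tests.

    Gaussian null data of total size ``n`` per replicate: two equal groups
    for Mann-Whitney, three for Kruskal-Wallis and Quade (one independent
    covariate), one independent pair for Spearman.
    """
    rng = np.random.default_rng(seed)
    rej = {"mann_whitney": 0, "kruskal_wallis": 0, "quade": 0, "spearman": 0}
    half, third = n // 2, n // 3
    groups3 = np.repeat([0, 1, 2], third)
    for _ in range(n_reps):
        x, y = rng.normal(size=half), rng.normal(size=half)
        rej["mann_whitney"] += mann_whitney_u(x, y).p_raw < alpha
        g = [rng.normal(size=third) for _ in range(3)]
        rej["kruskal_wallis"] += kruskal_wallis(g).p_raw < alpha
        resp = rng.normal(size=3 * third)
        cov = rng.normal(size=3 * third)
        rej["quade"] += quade_ancova(resp, groups3, [cov]).p_raw < alpha
        rej["spearman"] += spearman(rng.normal(size=n), rng.normal(size=n)).p_raw < alpha
    return {k: v / n_reps for k, v in rej.items()} | {"n_reps": n_reps, "n": n}


# ---------------------------------------------------------------------------
# End-to-end pattern recovery


def headline_pattern_recovery(
    n_seeds: int = 100, base_seed: int = 0, alpha: float = 0.05
) -> dict:
    """Recovery of the designed qualitative pattern at study-scale sizes.

    Per seed, a cohort is simulated with an LC elevation in PD(-)OH only, no
    SNc effect, and LC-to-MAP coupling in the (+)OH subgroups only; the
    subgroup comparisons and correlation battery are run.  Reports the
    fraction of seeds with (a) significant LC omnibus, null SNc omnibus and
    the three PD(-)OH Dunn pairs carrying the smallest raw p-values, (b)
    positive LC vs average-delta-MAP rho in both (+)OH strata, and (c) any
    FDR-significant positive such correlation in a (-)OH stratum (expected
    rare).
    """
    cfg = PipelineConfig()
    n_pattern = 0
    n_pos_coupling = 0
    n_false_coupling = 0
    for i in range(n_seeds):
        cohort = generate_cohort(headline_cohort_spec(base_seed + i))
        ensure_labels(cohort)
        frags = run_subgroup_comparisons(cohort, cfg)
        lc, snc = frags.get("LC"), frags.get("SNc")
        ok = (
            lc is not None
            and lc["omnibus"].p_raw < alpha
            and snc["omnibus"].p_raw >= alpha
            and lc["posthoc"] is not None
        )
        if ok:
            ranked = sorted(lc["posthoc"], key=lambda tr: tr.p_raw)
            smallest_pairs = [set(tr.notes["pair"]) for tr in ranked[:3]]
            ok = all("PD(-)OH" in pair for pair in smallest_pairs)
        n_pattern += bool(ok)

        corr, _ = run_correlation_battery(cohort)
        by_stratum = {
            c.pair[0]: c for c in corr if c.pair[1] == "avg_delta_map"
        }
        pos = all(
            s in by_stratum and by_stratum[s].rho > 0
            for s in ("PD(+)OH", "MSA(+)OH")
        )
        n_pos_coupling += pos
        false_hit = any(
            s in by_stratum
            and by_stratum[s].p_adjusted is not None
            and by_stratum[s].p_adjusted < alpha
            and by_stratum[s].rho > 0
            for s in ("PD(-)OH", "MSA(-)OH")
        )
        n_false_coupling += false_hit
    return {
        "pattern_fraction": n_pattern / n_seeds,
        "positive_coupling_fraction": n_pos_coupling / n_seeds,
        "false_coupling_fraction": n_false_coupling / n_seeds,
        "n": n_seeds,
    }
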