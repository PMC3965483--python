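"""Monte-Carlo validity checks for the statistical layer.

Self-contained simulations used to verify that the stratified permutation
test keeps its nominal type-I error, that Holm-Bonferroni controls the
familywise error rate over a seven-test family (the study's number of
species/stage comparisons), and that the imaging pipeline recovers % lipid
area from rendered micrographs.
"""

from __future__ import annotations

import numpy as np

from .imaging import measure
from .morphometry import MorphometricRecord, ScaleCalibration, quantify
from .stats import holm_bonferroni, kruskal_wallis, permutation_anova
from .synthetic import generate_micrograph

__all__ = [
    "permutation_type_one_error",
    "permutation_power",
    "holm_fwer",
    "imaging_recovery_errors",
]


def permutation_type_one_error(
    replicates: int = 500,
    n_per_group: int = 12,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation ANOVA under a global null.

    Both depth groups are drawn from the same normal distribution; the
    Monte-Carlo permutation path is forced (exhaustive_limit=1).
    """
    rng = np.random.default_rng(seed)
    depth = np.repeat(["shallow", "deep"], n_per_group)
    hits = 0
    for _ in range(replicates):
        y = rng.normal(0.0, 1.0, 2 * n_per_group)
        res = permutation_anova(
            y, depth, iterations=iterations,
            seed=int(rng.integers(2**31)), exhaustive_limit=1,
        )
        hits += res.p_raw <= alpha
    return hits / replicates


def permutation_power(
    effect: float,
    replicates: int = 100,
    n_per_group: int = 12,
    iterations: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate with a standardized mean shift between depth groups."""
    rng = np.random.default_rng(seed)
    depth = np.repeat(["shallow", "deep"], n_per_group)
    hits = 0
    for _ in range(replicates):
        y = np.concatenate([
            rng.normal(0.0, 1.0, n_per_group),
            rng.normal(effect, 1.0, n_per_group),
        ])
        res = permutation_anova(
            y, depth, iterations=iterations,
            seed=int(rng.integers(2**31)), exhaustive_limit=1,
        )
        hits += res.p_raw <= alpha
    return hits / replicates


def holm_fwer(
    replicates: int = 2000,
    n_tests: int = 7,
    n_per_group: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Familywise error rate of Holm over a global-null test family.

    Each family member is a two-group rank test on null normal data,
    mirroring the study's seven per-species depth comparisons.
    """
    rng = np.random.default_rng(seed)
    families_with_error = 0
    for _ in range(replicates):
        ps = []
        for _ in range(n_tests):
            a = rng.normal(size=n_per_group)
            b = rng.normal(size=n_per_group)
            ps.append(kruskal_wallis([a, b]).p)
        adjusted = holm_bonferroni(ps)
        families_with_error += any(p <= alpha for p in adjusted)
    return families_with_error / replicates


def imaging_recovery_errors(
    n_images: int = 50,
    noise_level: float = 0.03,
    scale: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Relative % lipid area errors of the full imaging round trip.

    Renders droplet- and sac-bearing individuals, measures them back, and
    returns |recovered - true| / true per image.
    """
    rng = np.random.default_rng(seed)
    cal = ScaleCalibration(microns_per_pixel=scale, grid_spacing=10.0)
    meta = dict(species_label="sp", stage_label="C5", site="red_sea",
                date_label="d", depth_layer_m=5.0)
    errors = []
    for i in range(n_images):
        pl = float(rng.uniform(0.8, 1.4))
        pw = pl * float(rng.uniform(0.3, 0.4))
        if i % 2 == 0:
            d1 = pw * float(rng.uniform(0.25, 0.4))
            d2 = pw * float(rng.uniform(0.2, 0.35))
            rec = MorphometricRecord("sp", "C5", "red_sea", "d", 5.0, pl, pw,
                                     droplet_diameters=(d1, d2))
        else:
            sl = pl * float(rng.uniform(0.35, 0.5))
            sw = pw * float(rng.uniform(0.35, 0.5))
            rec = MorphometricRecord("sp", "C5", "red_sea", "d", 5.0, pl, pw,
                                     sac_length=sl, sac_width=max(sw, 0.05))
        img = generate_micrograph(rec, scale=scale, noise_level=noise_level,
                                  seed=int(rng.integers(2**31)))
        truth = 100.0 * img.truth_lipid_area / img.truth_prosome_area
        got = quantify(measure(img.raster, cal, meta)).percent_lipid_area
        errors.append(abs(got - truth) / truth)
    return np.asarray(errors)
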