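"""End-to-end study orchestration: simulate → quantify → density → statistics.

``run_study`` executes the full analysis on a :class:`~copebuoy.io.StudyConfig`:
generate (or accept) per-group morphometric populations, quantify lipid
areas and volumes, attach individual body densities from the site CTD
casts, apply the configured exclusion filters, and run the depth-effect
permutation tests per species for each response family (% lipid area,
absolute lipid area, body density) with Holm adjustment across species
within each family.  Prosome-length rank tests and length–lipid
regressions round out the report.

``paper_like_study`` builds the default simulated design: seven
species/stage groups across three sites with the published per-group
sample sizes and prosome-length distributions (1091 individuals before
filtering), and illustrative lipid-content levels in which six of the
seven groups carry a true depth effect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .buoyancy import CTDProfile, density_at_depth
from .io import StudyConfig, FilterRule, apply_filters, write_results_csv
from .morphometry import quantify
from .stats import (
    DepthTestResult,
    attach_holm,
    kruskal_wallis,
    length_lipid_regression,
    permutation_anova,
)
from .synthetic import GroupSpec, default_archetypes, generate_ctd, generate_population

logger = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "quantify_records", "paper_like_study"]

RESPONSE_COLUMNS = {
    "percent_lipid_area": "percent_lipid_area",
    "lipid_area_mm2": "lipid_area_mm2",
    "body_density_g_cm3": "body_density_g_cm3",
}


@dataclass
class StudyReport:
    """All study outputs plus provenance."""

    individuals: pd.DataFrame  # one row per surviving individual
    lipid_table: list[DepthTestResult]  # % lipid area family
    robustness_table: list[DepthTestResult]  # absolute lipid area family
    density_tests: list[DepthTestResult]  # body density family
    density_table: pd.DataFrame  # per-group mean +- SD density
    length_table: pd.DataFrame  # per-group mean +- SD length + rank tests
    regression_table: pd.DataFrame  # per-species length vs lipid area OLS
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "individuals.csv", index=False)
        write_results_csv(self.lipid_table, out / "lipid_tests.csv")
        write_results_csv(self.robustness_table, out / "lipid_area_tests.csv")
        write_results_csv(self.density_tests, out / "density_tests.csv")
        self.density_table.to_csv(out / "density_groups.csv", index=False)
        self.length_table.to_csv(out / "length_groups.csv", index=False)
        self.regression_table.to_csv(out / "length_lipid_regressions.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def quantify_records(records) -> pd.DataFrame:
    """Quantify a list of morphometric records into the individuals table."""
    rows = []
    for rec in records:
        q = quantify(rec)
        rows.append({
            "species_label": rec.species_label,
            "stage_label": rec.stage_label,
            "site": rec.site,
            "date_label": rec.date_label,
            "depth_m": rec.depth_layer_m,
            "depth_layer": _depth_label(rec.depth_layer_m),
            "prosome_length_mm": rec.prosome_length,
            "prosome_width_mm": rec.prosome_width,
            "prosome_area_mm2": q.prosome_area,
            "lipid_area_mm2": q.lipid_area,
            "percent_lipid_area": q.percent_lipid_area,
            "prosome_volume_mm3": q.prosome_volume,
            "lipid_volume_mm3": q.lipid_volume,
            "lipid_volume_fraction": q.lipid_volume_fraction,
        })
    return pd.DataFrame(rows)


def _depth_label(z: float) -> str:
    return f"{z:g} m"


def _depth_class(df: pd.DataFrame) -> pd.Series:
    """Two-level depth factor (shallow/deep) per species.

    Sites tow at slightly different nominal depths on different dates
    (e.g. 6 vs 8 m); the depth-layer contrast of the statistical tests is
    the shallow/deep dichotomy, split at the species' depth-range midpoint.
    """
    out = pd.Series(index=df.index, dtype=object)
    for _, sub in df.groupby("species_label"):
        depths = np.sort(sub["depth_m"].unique())
        cut = 0.5 * (depths[0] + depths[-1])
        out.loc[sub.index] = np.where(sub["depth_m"] <= cut, "shallow", "deep")
    return out


def attach_density(df: pd.DataFrame, profiles: dict[tuple[str, str], CTDProfile],
                   config: StudyConfig) -> pd.DataFrame:
    """Add the modelled body density of each individual at its tow depth."""
    from .morphometry import LipidQuant

    densities = []
    for row in df.itertuples(index=False):
        profile = profiles[(row.site, row.date_label)]
        quant = LipidQuant(
            prosome_area=row.prosome_area_mm2,
            lipid_area=row.lipid_area_mm2,
            percent_lipid_area=row.percent_lipid_area,
            prosome_volume=row.prosome_volume_mm3,
            lipid_volume=row.lipid_volume_mm3,
            lipid_volume_fraction=row.lipid_volume_fraction,
        )
        densities.append(density_at_depth(
            quant, profile, row.depth_m, config.physics,
            f_tissue=config.f_tissue, rho_tissue=config.rho_tissue,
        ))
    out = df.copy()
    out["body_density_g_cm3"] = densities
    return out


def _group_summary(df: pd.DataFrame, value: str, name: str) -> pd.DataFrame:
    g = (
        df.groupby(["species_label", "date_label", "depth_layer"], sort=False)[value]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return g.rename(columns={"mean": f"{name}_mean", "std": f"{name}_sd", "count": "n"})


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated study; deterministic under a fixed config seed."""
    root = np.random.SeedSequence(config.seed)
    pop_seeds, ctd_seed_seq, stat_seed_seq = root.spawn(3)
    group_seeds = pop_seeds.spawn(len(config.groups))

    logger.info("stage simulate: %d groups", len(config.groups))
    records = []
    for spec, seq in zip(config.groups, group_seeds):
        records.extend(generate_population(spec, int(seq.generate_state(1)[0] % 2**31)))

    logger.info("stage quantify: %d individuals", len(records))
    df = quantify_records(records)

    logger.info("stage density")
    site_dates = sorted({(r.site, r.date_label) for r in records})
    ctd_children = ctd_seed_seq.spawn(len(site_dates))
    profiles = {
        key: generate_ctd(
            config.ctd[key[0]], config.ctd_noise_sd,
            int(seq.generate_state(1)[0] % 2**31),
        )
        for key, seq in zip(site_dates, ctd_children)
    }
    df = attach_density(df, profiles, config)

    n_before = len(df)
    df = apply_filters(df, config.filters)
    logger.info("stage filter: %d -> %d individuals", n_before, len(df))
    df["depth_class"] = _depth_class(df)

    logger.info("stage stats: responses %s", list(config.responses))
    species = list(dict.fromkeys(df["species_label"]))
    stat_children = iter(stat_seed_seq.spawn(len(species) * len(config.responses)))
    families: dict[str, list[DepthTestResult]] = {r: [] for r in config.responses}
    for response in config.responses:
        for sp in species:
            sub = df[df["species_label"] == sp]
            seq = next(stat_children)
            result = permutation_anova(
                sub[RESPONSE_COLUMNS[response]].to_numpy(),
                sub["depth_class"].to_numpy(),
                sub["date_label"].to_numpy(),
                iterations=config.iterations,
                seed=int(seq.generate_state(1)[0] % 2**31),
                exhaustive_limit=config.exhaustive_limit,
                species_label=sp,
                response=response,
            )
            families[response].append(result)
    families = {resp: attach_holm(res) for resp, res in families.items()}

    length_rows = _group_summary(df, "prosome_length_mm", "prosome_length")
    kw_by_species = {}
    for sp in species:
        sub = df[df["species_label"] == sp]
        groups = [g["prosome_length_mm"].to_numpy() for _, g in sub.groupby("depth_class")]
        if len(groups) >= 2:
            kw_by_species[sp] = kruskal_wallis(groups)
    length_rows["kw_H"] = length_rows["species_label"].map(
        lambda s: kw_by_species[s].H if s in kw_by_species else np.nan)
    length_rows["kw_p"] = length_rows["species_label"].map(
        lambda s: kw_by_species[s].p if s in kw_by_species else np.nan)

    regression_rows = []
    for sp in species:
        sub = df[df["species_label"] == sp]
        try:
            fit = length_lipid_regression(
                sub["prosome_length_mm"], sub["lipid_area_mm2"])
        except ValueError as exc:
            logger.warning("regression skipped for %s: %s", sp, exc)
            continue
        regression_rows.append({"species_label": sp, **fit})

    report = StudyReport(
        individuals=df,
        lipid_table=families.get("percent_lipid_area", []),
        robustness_table=families.get("lipid_area_mm2", []),
        density_tests=families.get("body_density_g_cm3", []),
        density_table=_group_summary(df, "body_density_g_cm3", "density"),
        length_table=length_rows,
        regression_table=pd.DataFrame(regression_rows),
        provenance={
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "iterations": config.iterations,
            "n_individuals": int(len(df)),
            "n_generated": int(n_before),
            "copebuoy_version": __version__,
            "numpy_version": np.__version__,
        },
    )
    return report


# ---------------------------------------------------------------------------
# default paper-shaped design


def _groups_paper_like(lipid_levels: dict | None = None) -> list[GroupSpec]:
    """Seven species/stage groups with the published n and length parameters.

    Per-group sample sizes and prosome-length means/SDs follow the field
    study's sampling table; lipid-content levels are illustrative defaults
    (deeper-richer in the Red Sea and Arctic C5 groups, shallower-richer in
    the Mediterranean groups, no effect in the Arctic C4 group) and may be
    overridden via ``lipid_levels[(species, date, depth_label)]``.
    """
    # (species, stage, site, geometry, w/l ratio,
    #  [(date, depth_m, n, pl_mean, pl_sd, lipid_mean, lipid_sd)])
    design = [
        ("M. clausi", "C5", "red_sea", "droplets", 0.30, [
            ("Jun-09", 5, 50, 1.112, 0.066, 2.0, 1.2),
            ("Jun-09", 20, 48, 1.113, 0.036, 3.5, 1.5),
            ("Jul-09", 5, 25, 1.372, 0.023, 2.0, 1.2),
            ("Jul-09", 20, 17, 1.365, 0.023, 3.5, 1.5),
            ("Sept-09", 5, 6, 1.118, 0.010, 2.0, 1.2),
            ("Sept-09", 20, 76, 1.110, 0.024, 3.5, 1.5),
            ("Aug-10", 25, 64, 0.735, 0.016, 3.0, 1.5),
            ("Aug-10", 65, 74, 0.724, 0.020, 4.5, 2.0),
        ]),
        ("C. vanus", "C5", "red_sea", "sac_ellipse", 0.32, [
            ("May-09", 5, 30, 1.18, 0.057, 2.5, 1.2),
            ("May-09", 20, 30, 1.15, 0.084, 4.5, 1.8),
            ("Jul-09", 5, 8, 0.83, 0.046, 2.5, 1.2),
            ("Jul-09", 20, 9, 1.02, 0.123, 4.5, 1.8),
            ("Sept-09", 5, 30, 0.81, 0.035, 2.5, 1.2),
            ("Sept-09", 20, 17, 1.00, 0.058, 4.5, 1.8),
        ]),
        ("C. furcatus", "male", "med_sea", "sac_contour", 0.32, [
            ("26.9.11", 7, 60, 0.621, 0.015, 6.0, 2.0),
            ("26.9.11", 20, 42, 0.619, 0.014, 4.0, 1.8),
            ("27.9.11", 6, 31, 0.634, 0.016, 6.0, 2.0),
            ("27.9.11", 20, 17, 0.617, 0.024, 4.0, 1.8),
        ]),
        ("C5 right", "C5", "med_sea", "sac_contour", 0.32, [
            ("26.9.11", 7, 48, 0.614, 0.020, 5.0, 2.0),
            ("26.9.11", 20, 42, 0.606, 0.018, 3.8, 1.8),
            ("27.9.11", 6, 21, 0.613, 0.023, 5.0, 2.0),
            ("27.9.11", 20, 15, 0.598, 0.022, 3.8, 1.8),
        ]),
        ("C5 left", "C5", "med_sea", "sac_contour", 0.32, [
            ("26.9.11", 7, 58, 0.612, 0.022, 6.0, 2.0),
            ("26.9.11", 20, 59, 0.607, 0.016, 4.0, 1.8),
            ("27.9.11", 6, 33, 0.618, 0.020, 6.0, 2.0),
            ("27.9.11", 20, 21, 0.602, 0.010, 4.0, 1.8),
        ]),
        ("C. glacialis C5", "C5", "arctic", "sac_contour", 0.36, [
            ("18.7.11", 8, 33, 3.18, 0.185, 18.0, 6.0),
            ("18.7.11", 20, 29, 3.22, 0.167, 24.0, 7.0),
            ("19.7.11", 6, 23, 3.35, 0.156, 18.0, 6.0),
            ("19.7.11", 15, 28, 3.35, 0.168, 24.0, 7.0),
        ]),
        ("C. glacialis C4", "C4", "arctic", "sac_contour", 0.36, [
            ("19.7.11", 6, 20, 2.48, 0.109, 8.0, 3.0),
            ("19.7.11", 15, 27, 2.45, 0.111, 8.0, 3.0),
        ]),
    ]
    groups = []
    for species, stage, site, geometry, ratio, rows in design:
        for date, depth, n, pl_mean, pl_sd, lp_mean, lp_sd in rows:
            if lipid_levels is not None:
                key = (species, date, depth)
                if key in lipid_levels:
                    lp_mean, lp_sd = lipid_levels[key]
            groups.append(GroupSpec(
                species_label=species,
                stage_label=stage,
                site=site,
                date_label=date,
                depth_layer_m=float(depth),
                n=n,
                prosome_length_mean=pl_mean,
                prosome_length_sd=pl_sd,
                width_to_length_ratio=ratio,
                lipid_pct_mean=lp_mean,
                lipid_pct_sd=lp_sd,
                lipid_geometry=geometry,
            ))
    return groups


def paper_like_study(seed: int, iterations: int = 5000,
                     lipid_levels: dict | None = None) -> StudyConfig:
    """Default study config: the seven-group, three-site simulated design.

    Includes the standard exclusion rule removing the deep-tow-only
    sampling date of *M. clausi* (the one date without a shallow layer)
    before statistics, mirroring the study protocol.
    """
    return StudyConfig(
        groups=_groups_paper_like(lipid_levels),
        ctd=default_archetypes(),
        seed=seed,
        iterations=iterations,
        filters=[FilterRule(
            conditions=(
                ("species_label", "==", "M. clausi"),
                ("date_label", "==", "Aug-10"),
            ),
            label="drop deep-tow-only date for M. clausi",
        )],
    )
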