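"""Study configuration and file formats (YAML config, CSV tables, JSON contours).

All tables are RFC-4180 CSV with required headers.  The morphometry table
holds one row per individual; digitised sac contours live in a companion
JSON file keyed by ``contour_id``.  CTD casts are ``depth_m, temp_C,
sal_psu`` tables.  Declarative exclusion filters (conjunctions of
field/op/value conditions) are applied with per-rule removal counts logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .buoyancy import CTDProfile, LipidPVTParams
from .morphometry import MorphometricRecord
from .synthetic import CTDArchetype, GroupSpec

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "FilterRule",
    "read_config",
    "write_config",
    "apply_filters",
    "read_morphometry_csv",
    "write_morphometry_csv",
    "read_ctd_csv",
    "write_ctd_csv",
    "write_results_csv",
    "read_results_csv",
]

MORPH_COLUMNS = [
    "species_label", "stage_label", "site", "date_label", "depth_m",
    "prosome_length_mm", "prosome_width_mm", "geometry_kind",
    "droplet_diameters_mm", "sac_length_mm", "sac_width_mm", "contour_id",
]

CTD_COLUMNS = ["depth_m", "temp_C", "sal_psu"]

RESPONSES = ("percent_lipid_area", "lipid_area_mm2", "body_density_g_cm3")


@dataclass(frozen=True)
class FilterRule:
    """Conjunction of conditions; matching rows are excluded."""

    conditions: tuple[tuple[str, str, object], ...]  # (field, op, value)
    label: str = ""

    _OPS = {
        "==": lambda col, v: col == v,
        "!=": lambda col, v: col != v,
        "<": lambda col, v: col < v,
        "<=": lambda col, v: col <= v,
        ">": lambda col, v: col > v,
        ">=": lambda col, v: col >= v,
        "in": lambda col, v: col.isin(list(v)),
    }

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=df.index)
        for fld, op, value in self.conditions:
            if fld not in df.columns:
                raise KeyError(f"filter references unknown field {fld!r}")
            if op not in self._OPS:
                raise ValueError(f"unknown filter operator {op!r}")
            m &= self._OPS[op](df[fld], value)
        return m


@dataclass
class StudyConfig:
    """Full description of one simulated (or ingested) study."""

    groups: list[GroupSpec]
    ctd: dict[str, CTDArchetype]
    seed: int
    physics: LipidPVTParams = field(default_factory=LipidPVTParams)
    f_tissue: float = 0.2
    rho_tissue: float = 1.08
    ctd_noise_sd: float = 0.05
    iterations: int = 5000
    exhaustive_limit: int = 20_000
    responses: tuple[str, ...] = RESPONSES
    filters: list[FilterRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        sites = {g.site for g in self.groups}
        missing = sites - set(self.ctd)
        if missing:
            raise ValueError(f"no CTD entry for site(s): {sorted(missing)}")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown response(s): {sorted(unknown)}")

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(_config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _config_to_dict(config: StudyConfig) -> dict:
    return {
        "seed": config.seed,
        "groups": [asdict(g) for g in config.groups],
        "ctd": {
            site: {
                "depth_grid": list(a.depth_grid),
                "temperature": list(a.temperature),
                "salinity": list(a.salinity),
            }
            for site, a in config.ctd.items()
        },
        "physics": {
            "lipid_pvt": asdict(config.physics),
            "f_tissue": config.f_tissue,
            "rho_tissue": config.rho_tissue,
            "ctd_noise_sd": config.ctd_noise_sd,
        },
        "stats": {
            "iterations": config.iterations,
            "exhaustive_limit": config.exhaustive_limit,
            "responses": list(config.responses),
        },
        "filters": [
            {"label": r.label, "conditions": [list(c) for c in r.conditions]}
            for r in config.filters
        ],
    }


def write_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def read_config(path) -> StudyConfig:
    """Parse a study YAML into a validated :class:`StudyConfig`.

    CTD entries may be inline archetypes or paths to CTD CSV files
    (resolved relative to the YAML's directory).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if "seed" not in raw:
        raise ValueError("config must provide a seed")
    groups = [GroupSpec(**g) for g in raw.get("groups", [])]
    ctd: dict[str, CTDArchetype] = {}
    for site, entry in (raw.get("ctd") or {}).items():
        if isinstance(entry, str):
            profile = read_ctd_csv(path.parent / entry)
            ctd[site] = CTDArchetype(
                site=site,
                depth_grid=profile.depth,
                temperature=profile.temperature,
                salinity=profile.salinity,
            )
        else:
            ctd[site] = CTDArchetype(site=site, **entry)
    physics_raw = raw.get("physics", {})
    pvt = LipidPVTParams(**physics_raw.get("lipid_pvt", {}))
    stats_raw = raw.get("stats", {})
    filters = [
        FilterRule(
            conditions=tuple(tuple(c) for c in f["conditions"]),
            label=f.get("label", ""),
        )
        for f in raw.get("filters", [])
    ]
    return StudyConfig(
        groups=groups,
        ctd=ctd,
        seed=int(raw["seed"]),
        physics=pvt,
        f_tissue=float(physics_raw.get("f_tissue", 0.2)),
        rho_tissue=float(physics_raw.get("rho_tissue", 1.08)),
        ctd_noise_sd=float(physics_raw.get("ctd_noise_sd", 0.05)),
        iterations=int(stats_raw.get("iterations", 5000)),
        exhaustive_limit=int(stats_raw.get("exhaustive_limit", 20_000)),
        responses=tuple(stats_raw.get("responses", RESPONSES)),
        filters=filters,
    )


def apply_filters(df: pd.DataFrame, rules) -> pd.DataFrame:
    """Drop rows matching any exclusion rule; log per-rule removal counts."""
    out = df
    for i, rule in enumerate(rules):
        m = rule.mask(out)
        n_removed = int(m.sum())
        logger.info(
            "filter %s: removed %d of %d rows",
            rule.label or f"#{i + 1}", n_removed, len(out),
        )
        out = out[~m]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# morphometry table

def write_morphometry_csv(records, csv_path, contours_path=None) -> None:
    """One row per individual; contours to a companion JSON keyed by id."""
    rows = []
    contours: dict[str, list] = {}
    for i, rec in enumerate(records):
        contour_id = ""
        if rec.sac_contour is not None:
            contour_id = f"c{i:05d}"
            contours[contour_id] = [[x, y] for x, y in rec.sac_contour]
        rows.append({
            "species_label": rec.species_label,
            "stage_label": rec.stage_label,
            "site": rec.site,
            "date_label": rec.date_label,
            "depth_m": rec.depth_layer_m,
            "prosome_length_mm": rec.prosome_length,
            "prosome_width_mm": rec.prosome_width,
            "geometry_kind": rec.geometry_kind,
            "droplet_diameters_mm": (
                ";".join(repr(d) for d in rec.droplet_diameters)
                if rec.droplet_diameters is not None else ""
            ),
            "sac_length_mm": "" if rec.sac_length is None else rec.sac_length,
            "sac_width_mm": "" if rec.sac_width is None else rec.sac_width,
            "contour_id": contour_id,
        })
    pd.DataFrame(rows, columns=MORPH_COLUMNS).to_csv(csv_path, index=False)
    if contours or contours_path is not None:
        if contours_path is None:
            raise ValueError("records contain contours but no contours_path given")
        Path(contours_path).write_text(json.dumps(contours))


def read_morphometry_csv(csv_path, contours_path=None) -> list[MorphometricRecord]:
    df = pd.read_csv(csv_path, dtype={"droplet_diameters_mm": str, "contour_id": str})
    missing = [c for c in MORPH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"morphometry CSV missing column(s): {missing}")
    contours = {}
    if contours_path is not None and Path(contours_path).exists():
        contours = json.loads(Path(contours_path).read_text())
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kind = row.geometry_kind
            geometry: dict = {}
            if kind == "droplets":
                raw = "" if pd.isna(row.droplet_diameters_mm) else row.droplet_diameters_mm
                geometry["droplet_diameters"] = tuple(
                    float(tok) for tok in raw.split(";") if tok
                )
            elif kind == "sac_ellipse":
                geometry["sac_length"] = float(row.sac_length_mm)
                geometry["sac_width"] = float(row.sac_width_mm)
            elif kind == "sac_contour":
                cid = row.contour_id
                if cid not in contours:
                    raise ValueError(f"contour id {cid!r} not found in contour JSON")
                geometry["sac_contour"] = tuple((x, y) for x, y in contours[cid])
            elif kind != "none":
                raise ValueError(f"unknown geometry_kind {kind!r}")
            records.append(MorphometricRecord(
                species_label=row.species_label,
                stage_label=row.stage_label,
                site=row.site,
                date_label=row.date_label,
                depth_layer_m=float(row.depth_m),
                prosome_length=float(row.prosome_length_mm),
                prosome_width=float(row.prosome_width_mm),
                **geometry,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed morphometry row at line {line}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# CTD table

def write_ctd_csv(profile: CTDProfile, path) -> None:
    pd.DataFrame({
        "depth_m": profile.depth,
        "temp_C": profile.temperature,
        "sal_psu": profile.salinity,
    }).to_csv(path, index=False)


def read_ctd_csv(path) -> CTDProfile:
    df = pd.read_csv(path)
    missing = [c for c in CTD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CTD CSV missing column(s): {missing}")
    depths = df["depth_m"].to_numpy(dtype=float)
    if np.any(np.diff(depths) == 0):
        raise ValueError("CTD CSV contains duplicated depths")
    if np.any(np.diff(depths) < 0):
        raise ValueError("CTD CSV depths must be increasing")
    return CTDProfile(
        depth=tuple(depths),
        temperature=tuple(df["temp_C"].astype(float)),
        salinity=tuple(df["sal_psu"].astype(float)),
    )


# ---------------------------------------------------------------------------
# results table (permutation-test outcomes)

RESULT_COLUMNS = [
    "species_label", "response", "F_obs", "df_depth", "df_resid", "n",
    "iterations", "exact", "p_raw", "p_adjusted", "seed", "scheme",
]


def write_results_csv(results, path) -> None:
    """Serialise DepthTestResults (Table 2/4 analogue plus metadata)."""
    rows = [{
        "species_label": r.species_label,
        "response": r.response,
        "F_obs": r.F_obs,
        "df_depth": r.df_depth,
        "df_resid": r.df_resid,
        "n": r.n,
        "iterations": r.iterations,
        "exact": r.exact,
        "p_raw": r.p_raw,
        "p_adjusted": "" if r.p_adjusted is None else r.p_adjusted,
        "seed": "" if r.seed is None else r.seed,
        "scheme": "within-date-stratum permutation",
    } for r in results]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results CSV missing column(s): {missing}")
    return df
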