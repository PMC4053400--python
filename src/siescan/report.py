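"""Report assembly: component-table ingestion, comparisons, pipeline driver.

Tables use the row schema ``dE_vdw, dE_c, gamma_dMSA, dG_R, dG_bind`` (one
column per system, cells ``mean±err``).  All "increase/decrease" statements
are emitted as explicit signed differences with the minuend and subtrahend
named in the column header, since prose sign conventions are ambiguous.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from siescan import constants
from siescan.alanine import MutationSpec, alanine_scan_report, mutate_trajectory
from siescan.dynamics import RegionSpec, dccm, region_summary, rmsf, rmsd_series
from siescan.energetics import (
    EnergyComponents,
    SIECoefficients,
    sie_combine,
    sie_trajectory,
)
from siescan.hbond import (
    HBondEnergyModel,
    PolarInteractionModel,
    complex_hbond_total,
    detect_hbonds,
    distance_distribution,
    hbond_energy_mean,
    hydrophobic_contacts,
    polar_total,
    residue_polar_energy,
)
from siescan.structure_io import (
    MolecularSystem,
    Trajectory,
    assign_parameters,
    read_parameter_table,
    read_pdb,
    read_trajectory,
    write_parameter_table,
    write_pdb,
    write_trajectory,
)
from siescan.synth import (
    SyntheticSpec,
    build_toy_complex,
    gaussian_trajectory,
)

logger = logging.getLogger(__name__)

#: Required rows of a components table, in display order.
COMPONENT_ROWS = ("dE_vdw", "dE_c", "gamma_dMSA", "dG_R", "dG_bind")

#: Map from table row name to EnergyComponents attribute.
_ROW_ATTR = {
    "dE_vdw": "e_vdw",
    "dE_c": "e_coulomb",
    "gamma_dMSA": "gamma_msa_term",
    "dG_R": "g_reaction",
    "dG_bind": "dg_bind",
}

_PM_SPLIT = re.compile(r"±|\+/-|\+-")


class TableFormatError(ValueError):
    """Raised for malformed component/energy tables."""


# ---------------------------------------------------------------------------
# mean±err cells
# ---------------------------------------------------------------------------

def parse_cell(cell: str) -> Tuple[float, float]:
    """Parse a ``mean±err`` cell (err optional) into floats.

    Unicode minus signs are normalized; ``"−33.35±0.19"`` -> (-33.35, 0.19).
    """
    text = str(cell).strip().replace("−", "-")
    if not text:
        raise TableFormatError("empty cell")
    parts = _PM_SPLIT.split(text)
    try:
        mean = float(parts[0])
        err = float(parts[1]) if len(parts) > 1 and parts[1].strip() else 0.0
    except ValueError as exc:
        raise TableFormatError(f"malformed cell {cell!r}") from exc
    return mean, err


def format_cell(mean: float, err: float = 0.0) -> str:
    if err:
        return f"{mean:.10g}±{err:.10g}"
    return f"{mean:.10g}"


# ---------------------------------------------------------------------------
# Components tables
# ---------------------------------------------------------------------------

def read_energy_table(path: str | Path) -> pd.DataFrame:
    """Raw component table: index = row names, values = (mean, err) tuples.

    Cells that are empty/NaN stay NaN.  Malformed cells raise
    :class:`TableFormatError` naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    for row in df.index:
        for col in df.columns:
            cell = df.loc[row, col]
            if pd.isna(cell) or str(cell).strip() == "":
                out.loc[row, col] = math.nan
                continue
            try:
                out.loc[row, col] = parse_cell(cell)
            except TableFormatError as exc:
                raise TableFormatError(
                    f"{path}: row {row!r}, column {col!r}: {exc}") from exc
    return out


def ingest_components_table(path: str | Path) -> Dict[str, EnergyComponents]:
    """Parse a components table into one :class:`EnergyComponents` per system.

    The table must contain all of ``dE_vdw, dE_c, gamma_dMSA, dG_R,
    dG_bind``; additional rows (e.g. a stated ddG or experimental dG) are
    ignored here and can be read via :func:`read_energy_table`.
    """
    raw = read_energy_table(path)
    missing = [r for r in COMPONENT_ROWS if r not in raw.index]
    if missing:
        raise TableFormatError(f"{path}: missing required rows {missing}")
    out: Dict[str, EnergyComponents] = {}
    for col in raw.columns:
        vals = {}
        for row in COMPONENT_ROWS:
            cell = raw.loc[row, col]
            if not isinstance(cell, tuple):
                raise TableFormatError(
                    f"{path}: row {row!r}, column {col!r}: empty cell")
            vals[row] = cell
        out[col] = EnergyComponents(
            e_vdw=vals["dE_vdw"][0], e_vdw_sem=vals["dE_vdw"][1],
            e_coulomb=vals["dE_c"][0], e_coulomb_sem=vals["dE_c"][1],
            gamma_msa_term=vals["gamma_dMSA"][0],
            gamma_msa_term_sem=vals["gamma_dMSA"][1],
            g_reaction=vals["dG_R"][0], g_reaction_sem=vals["dG_R"][1],
            dg_bind=vals["dG_bind"][0], dg_bind_sem=vals["dG_bind"][1],
        )
    return out


def write_components_table(components: Mapping[str, EnergyComponents],
                           path: str | Path) -> None:
    cols = {}
    for name, comp in components.items():
        d = comp.as_dict()
        cols[name] = {row: format_cell(*d[row]) for row in COMPONENT_ROWS}
    df = pd.DataFrame(cols)
    df.index.name = "energy"
    df = df.loc[list(COMPONENT_ROWS)]
    df.to_csv(path, sep="\t")


def component_difference(components: Mapping[str, EnergyComponents],
                         row: str, minuend: str, subtrahend: str) -> float:
    """Signed difference ``row(minuend) - row(subtrahend)``, kcal/mol."""
    attr = _ROW_ATTR[row]
    return (getattr(components[minuend], attr)
            - getattr(components[subtrahend], attr))


def comparison_table(components: Mapping[str, EnergyComponents],
                     pairs: Sequence[Tuple[str, str]] | None = None
                     ) -> pd.DataFrame:
    """Pairwise component differences; columns name minuend and subtrahend.

    Default pairs: every ordered pair of distinct systems.
    """
    names = list(components)
    if pairs is None:
        pairs = [(a, b) for a in names for b in names if a != b]
    data = {}
    for a, b in pairs:
        col = f"{a}_minus_{b}"
        data[col] = [component_difference(components, row, a, b)
                     for row in COMPONENT_ROWS]
    df = pd.DataFrame(data, index=list(COMPONENT_ROWS))
    df.index.name = "energy"
    return df


def wild_mutant_pairs(names: Sequence[str]) -> List[Tuple[str, str]]:
    """Match ``X-wild`` / ``X-mutant`` column pairs by shared prefix."""
    pairs = []
    for n in names:
        if n.endswith("-wild"):
            m = n[: -len("wild")] + "mutant"
            if m in names:
                pairs.append((n, m))
    return pairs


def ddg_table(components: Mapping[str, EnergyComponents],
              stated: Mapping[str, float] | None = None,
              tol: float = 0.02) -> pd.DataFrame:
    """ddG = dG(mutant) - dG(wild) per matched pair, with consistency flags.

    If a ``stated`` ddG disagrees with the recomputation beyond ``tol`` the
    row is flagged and the recomputed value reported.
    """
    rows = []
    for wild, mutant in wild_mutant_pairs(list(components)):
        ddg = components[mutant].dg_bind - components[wild].dg_bind
        name = wild[: -len("-wild")]
        flag = ""
        if stated and name in stated and not math.isnan(stated[name]):
            if abs(stated[name] - ddg) > tol:
                flag = (f"stated {stated[name]:+.2f} inconsistent with dG "
                        f"columns; recomputed {ddg:+.2f} used")
        rows.append({"system": name, "wild": components[wild].dg_bind,
                     "mutant": components[mutant].dg_bind,
                     "ddG_bind": ddg, "flag": flag})
    return pd.DataFrame(rows, columns=["system", "wild", "mutant",
                                       "ddG_bind", "flag"])


# ---------------------------------------------------------------------------
# Per-bond / per-residue tables (totals)
# ---------------------------------------------------------------------------

def read_bond_table(path: str | Path) -> pd.DataFrame:
    """Per-bond energy table: columns ``complex, bond, energy`` (mean±sd)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"complex", "bond", "energy"}
    if not need.issubset(df.columns):
        raise TableFormatError(f"{path}: need columns {sorted(need)}")
    parsed = df.copy()
    parsed[["mean", "sd"]] = [parse_cell(c) for c in df["energy"]]
    return parsed


def hbond_totals(path: str | Path) -> pd.Series:
    """Per-complex sum of hydrogen-bond energies from a bond table."""
    df = read_bond_table(path)
    return df.groupby("complex", sort=False)["mean"].agg(
        lambda x: complex_hbond_total(list(x)))


def read_residue_table(path: str | Path) -> pd.DataFrame:
    """Per-residue polar table: columns ``complex, residue, wild, mutant``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"complex", "residue", "wild", "mutant"}
    if not need.issubset(df.columns):
        raise TableFormatError(f"{path}: need columns {sorted(need)}")
    parsed = df.copy()
    parsed[["wild_mean", "wild_err"]] = [parse_cell(c) for c in df["wild"]]
    parsed[["mutant_mean", "mutant_err"]] = [parse_cell(c) for c in df["mutant"]]
    return parsed


def polar_totals(path: str | Path, column: str = "wild_mean") -> pd.Series:
    """Per-complex sum of per-residue polar energies."""
    df = read_residue_table(path)
    return df.groupby("complex", sort=False)[column].agg(
        lambda x: polar_total(list(x)))


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_ALL_STAGES = ("simulate", "rmsd", "dccm", "rmsf", "sie", "hbonds", "polar",
               "contacts", "alascan", "report")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of key: value entries")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Dict[str, Path]:
    """Run the configured analysis stages, writing a deterministic bundle.

    Returns a mapping from artifact name to path.  All inputs are checked
    before any computation starts; every stage logs one structured line with
    input hashes and the parameters in effect.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate", "sie"])
    unknown = [s for s in stages if s not in _ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {_ALL_STAGES}")

    # ---- validate inputs up front -----------------------------------------
    needs_system = any(s in stages for s in _ALL_STAGES[1:-1])
    for key in ("structure", "trajectory", "parameters", "components_table",
                "hbond_table", "polar_table"):
        if key in cfg and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"config {key}: {cfg[key]} does not exist")
    if needs_system and "simulate" not in stages:
        for key in ("structure", "trajectory", "parameters"):
            if key not in cfg:
                raise ValueError(
                    f"config needs {key!r} (or add the simulate stage)")

    artifacts: Dict[str, Path] = {}
    system = traj = None

    def log_stage(name: str, **params) -> None:
        hashes = {k: _sha256(Path(cfg[k])) for k in
                  ("structure", "trajectory", "parameters")
                  if k in cfg and Path(cfg[k]).exists()}
        logger.info("stage=%s params=%s inputs=%s", name,
                    json.dumps(params, sort_keys=True, default=str),
                    json.dumps(hashes, sort_keys=True))

    if "simulate" in stages:
        spec = SyntheticSpec(
            n_residues=int(cfg.get("n_residues", 8)),
            n_frames=int(cfg.get("n_frames", 100)),
            seed=int(cfg.get("seed", 0)),
            sigma=cfg.get("sigma", 0.3),
        )
        log_stage("simulate", seed=spec.seed, n_frames=spec.n_frames)
        system, mapping = build_toy_complex(spec)
        traj = gaussian_trajectory(system, spec)
        write_pdb(system, out / "structure.pdb")
        write_trajectory(system, traj, out / "trajectory.pdb")
        write_parameter_table(mapping, out / "parameters.tsv")
        artifacts["structure"] = out / "structure.pdb"
        artifacts["trajectory"] = out / "trajectory.pdb"
        artifacts["parameters"] = out / "parameters.tsv"
        cfg.setdefault("structure", str(out / "structure.pdb"))
        cfg.setdefault("trajectory", str(out / "trajectory.pdb"))
        cfg.setdefault("parameters", str(out / "parameters.tsv"))

    if needs_system and system is None:
        system = read_pdb(cfg["structure"])
        system = assign_parameters(system,
                                   read_parameter_table(cfg["parameters"]))
        traj = read_trajectory(cfg["trajectory"], system,
                               frame_interval=float(cfg.get("frame_interval", 2.0)))

    ca = system.ca_indices() if system is not None else None
    ca_labels = ([f"{system.atoms[i].res_name}{system.atoms[i].res_id}"
                  for i in ca] if system is not None else None)
    res_ids = ([system.atoms[i].res_id for i in ca]
               if system is not None else None)

    if "rmsd" in stages:
        log_stage("rmsd")
        series = rmsd_series(traj, system.coords, ca)
        df = pd.DataFrame({"frame": np.arange(traj.n_frames),
                           "time_ps": np.arange(traj.n_frames) * traj.frame_interval,
                           "rmsd": series})
        df.to_csv(out / "rmsd.tsv", sep="\t", index=False)
        (out / "rmsd_mean.json").write_text(
            json.dumps({"mean_rmsd": float(series.mean())}, indent=1))
        artifacts["rmsd"] = out / "rmsd.tsv"

    if "dccm" in stages:
        log_stage("dccm", n_ca=len(ca))
        matrix = dccm(traj, ca, labels=ca_labels)
        matrix.to_tsv(out / "dccm.tsv")
        matrix.to_json(out / "dccm.json")
        artifacts["dccm"] = out / "dccm.tsv"
        if "regions" in cfg:
            spec = RegionSpec.from_config(cfg["regions"])
            region_summary(matrix, spec, res_ids).to_csv(
                out / "dccm_regions.tsv", sep="\t", index=False)
            artifacts["dccm_regions"] = out / "dccm_regions.tsv"

    if "rmsf" in stages:
        log_stage("rmsf", n_ca=len(ca))
        values = rmsf(traj, ca)
        df = pd.DataFrame({"residue": ca_labels, "rmsf": values})
        df.to_csv(out / "rmsf.tsv", sep="\t", index=False)
        artifacts["rmsf"] = out / "rmsf.tsv"
        if "regions" in cfg:
            spec = RegionSpec.from_config(cfg["regions"])
            region_summary(values, spec, res_ids).to_csv(
                out / "rmsf_regions.tsv", sep="\t", index=False)
            artifacts["rmsf_regions"] = out / "rmsf_regions.tsv"

    coeffs = SIECoefficients()
    sie_kwargs = dict(
        snapshot_stride=int(cfg.get("snapshot_stride", 1)),
        rf_spacing=float(cfg.get("rf_spacing", 0.8)),
        rf_margin=float(cfg.get("rf_margin", 6.0)),
        sasa_points=int(cfg.get("sasa_points", 240)),
    )

    if "sie" in stages:
        log_stage("sie", **sie_kwargs)
        comp = sie_trajectory(traj, system, coeffs, **sie_kwargs)
        write_components_table({cfg.get("system_name", "complex"): comp},
                               out / "sie.tsv")
        (out / "sie.json").write_text(json.dumps(
            {k: list(v) for k, v in comp.as_dict().items()}
            | {"n_snapshots": comp.n_snapshots}, indent=1))
        artifacts["sie"] = out / "sie.tsv"

    if "hbonds" in stages:
        log_stage("hbonds")
        model = HBondEnergyModel()
        bonds = detect_hbonds(traj, system)
        rows = []
        for b in bonds:
            mean, sd = hbond_energy_mean(b, model)
            rows.append({"bond": b.label, "occupancy": b.occupancy,
                         "energy": format_cell(mean, sd)})
            dist = distance_distribution(b)
            dist.to_frame().to_csv(
                out / f"hbond_hist_{len(rows)}.tsv", sep="\t", index=False)
        df = pd.DataFrame(rows, columns=["bond", "occupancy", "energy"])
        df.to_csv(out / "hbonds.tsv", sep="\t", index=False)
        total = complex_hbond_total(
            [parse_cell(r["energy"])[0] for r in rows])
        (out / "hbond_total.json").write_text(
            json.dumps({"total": total, "n_bonds": len(rows)}, indent=1))
        artifacts["hbonds"] = out / "hbonds.tsv"

    if "polar" in stages:
        residues = cfg.get("polar_residues")
        if residues is None:
            residues = sorted({a.res_id for a in system.atoms
                               if a.res_name in ("ARG", "LYS", "HIS")})
        log_stage("polar", residues=residues)
        model = PolarInteractionModel()
        rows = []
        for rid in residues:
            mean, sem = residue_polar_energy(traj, system, int(rid),
                                             model=model)
            label = next(a.res_name for a in system.atoms if a.res_id == rid)
            rows.append({"residue": f"{label}{rid}",
                         "energy": format_cell(mean, sem)})
        df = pd.DataFrame(rows, columns=["residue", "energy"])
        df.to_csv(out / "polar.tsv", sep="\t", index=False)
        total = polar_total([parse_cell(r["energy"])[0] for r in rows])
        (out / "polar_total.json").write_text(
            json.dumps({"total": total, "n_residues": len(rows)}, indent=1))
        artifacts["polar"] = out / "polar.tsv"

    if "contacts" in stages:
        log_stage("contacts")
        profile = hydrophobic_contacts(traj, system)
        occ = profile.occupancy
        occ.rename("occupancy").to_csv(out / "contacts.tsv", sep="\t",
                                       index_label="residue")
        artifacts["contacts"] = out / "contacts.tsv"

    if "alascan" in stages:
        if "mutate" not in cfg:
            raise ValueError("alascan stage needs a 'mutate' entry like A:4")
        mspec = MutationSpec.parse(str(cfg["mutate"]))
        log_stage("alascan", mutate=str(cfg["mutate"]), **sie_kwargs)
        mutant, mtraj = mutate_trajectory(traj, system, mspec)
        write_pdb(mutant, out / "mutant.pdb")
        wild_comp = sie_trajectory(traj, system, coeffs, **sie_kwargs)
        mut_comp = sie_trajectory(mtraj, mutant, coeffs, **sie_kwargs)
        table = alanine_scan_report(wild_comp, mut_comp)
        table.to_csv(out / "alascan.tsv", sep="\t", index=False)
        write_components_table({"wild": wild_comp, "mutant": mut_comp},
                               out / "alascan_components.tsv")
        artifacts["alascan"] = out / "alascan.tsv"

    if "report" in stages:
        if "components_table" not in cfg:
            raise ValueError("report stage needs a 'components_table' entry")
        log_stage("report", components_table=str(cfg["components_table"]))
        comps = ingest_components_table(cfg["components_table"])
        comparison_table(comps).to_csv(out / "comparisons.tsv", sep="\t")
        raw = read_energy_table(cfg["components_table"])
        stated = {}
        if "ddG_bind" in raw.index:
            for col in raw.columns:
                cell = raw.loc["ddG_bind", col]
                if isinstance(cell, tuple) and col.endswith("-mutant"):
                    stated[col[: -len("-mutant")]] = cell[0]
        ddg_table(comps, stated or None).to_csv(
            out / "ddg.tsv", sep="\t", index=False)
        artifacts["comparisons"] = out / "comparisons.tsv"
        artifacts["ddg"] = out / "ddg.tsv"
        if "hbond_table" in cfg:
            hbond_totals(cfg["hbond_table"]).rename("total").to_csv(
                out / "hbond_totals.tsv", sep="\t", index_label="complex")
            artifacts["hbond_totals"] = out / "hbond_totals.tsv"
        if "polar_table" in cfg:
            polar_totals(cfg["polar_table"]).rename("total").to_csv(
                out / "polar_totals.tsv", sep="\t", index_label="complex")
            artifacts["polar_totals"] = out / "polar_totals.tsv"

    return artifacts
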