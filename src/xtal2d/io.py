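"""File formats: reflection tables, CCP4/MRC 2D maps, counts, reports, plots.

Reflection tables are plain text, one record per line ``h k amplitude
phase_deg`` with header comments carrying the cell, resolution limit and
Friedel convention.  Maps are written as CCP4/MRC volumes with nz = 1 (the
third cell edge is a nominal 10 Å slab) plus a JSON sidecar with the exact
2D metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .diffmaps import DifferenceMap
from .geometry import UnitCell2D
from .mapsynth import ProjectionMap
from .reflections import ReflectionError, StructureFactorSet
from .titration import FitResult, TitrationSeries


class FormatError(ValueError):
    """Malformed input files."""


_SLAB_C = 10.0   # nominal thickness (Å) of the 2D slab in 3D map headers


# ---------------------------------------------------------------------------
# reflection tables
def write_reflections(sf: StructureFactorSet, path) -> None:
    lines = [
        f"# cell {sf.cell.a:.6g} {sf.cell.b:.6g} {sf.cell.gamma:.6g}",
        f"# dmin {sf.d_min:.6g}",
        f"# friedel {sf.friedel}",
    ]
    for h, k, a, p in zip(sf.h, sf.k, sf.amplitude, sf.phase_deg):
        lines.append(f"{h:d} {k:d} {a:.8e} {p:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path) -> StructureFactorSet:
    cell = d_min = None
    friedel = "+"
    h, k, amp, ph = [], [], [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields and fields[0] == "cell":
                a, b, g = (float(x) for x in fields[1:4])
                cell = UnitCell2D(a=a, b=b, gamma=g)
            elif fields and fields[0] == "dmin":
                d_min = float(fields[1])
            elif fields and fields[0] == "friedel":
                friedel = fields[1]
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"{path}:{ln}: expected 'h k amplitude phase'")
        h.append(int(fields[0]))
        k.append(int(fields[1]))
        amp.append(float(fields[2]))
        ph.append(float(fields[3]))
    if cell is None or d_min is None:
        raise FormatError(f"{path}: missing '# cell' or '# dmin' header")
    try:
        return StructureFactorSet(
            cell=cell, d_min=d_min, h=np.array(h), k=np.array(k),
            amplitude=np.array(amp), phase_deg=np.array(ph), friedel=friedel,
        )
    except ReflectionError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# CCP4/MRC maps (2D slabs, nz = 1)
def write_map(pmap: ProjectionMap | DifferenceMap, path) -> None:
    nx, ny = pmap.grid.shape
    grid = gemmi.FloatGrid(nx, ny, 1)
    grid.set_unit_cell(
        gemmi.UnitCell(pmap.cell.a, pmap.cell.b, _SLAB_C, 90.0, 90.0, pmap.cell.gamma)
    )
    np.asarray(grid)[:, :, 0] = pmap.grid.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
    sidecar = {
        "cell": {"a": pmap.cell.a, "b": pmap.cell.b, "gamma": pmap.cell.gamma},
        "mean": float(pmap.grid.mean()),
        "sigma": float(pmap.grid.std()),
    }
    if isinstance(pmap, DifferenceMap):
        sidecar["contour_step"] = pmap.contour_step
        sidecar["background_levels"] = pmap.background_levels
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_map(path) -> ProjectionMap | DifferenceMap:
    m = gemmi.read_ccp4_map(str(path))
    if m.grid.nw != 1:
        raise FormatError(f"{path}: expected a 2D map (nz = 1), got nz = {m.grid.nw}")
    uc = m.grid.unit_cell
    cell = UnitCell2D(a=uc.a, b=uc.b, gamma=uc.gamma)
    grid = np.array(m.grid)[:, :, 0].astype(float)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        cell = UnitCell2D(**meta["cell"])
        if "contour_step" in meta:
            return DifferenceMap(
                grid=grid, cell=cell, contour_step=meta["contour_step"],
                background_levels=meta.get("background_levels", 0),
            )
    return ProjectionMap(grid=grid, cell=cell)


# ---------------------------------------------------------------------------
# counts, fits, ground truth
def write_counts_csv(
    raw: TitrationSeries, corrected: TitrationSeries, path
) -> None:
    df_raw = raw.to_dataframe().rename(columns={"peak_to_trough": "raw"})
    df_cor = corrected.to_dataframe().rename(columns={"peak_to_trough": "corrected"})
    df = df_raw.drop(columns=["corrected"]).merge(
        df_cor.drop(columns=["corrected"]), on=["ph", "na_mM", "region"]
    )
    df.to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_report(fits: dict[str, FitResult], path) -> None:
    payload = {
        rid: {
            "kd_app_mM": f.kd_app,
            "h_max_levels": f.h_max,
            "rss": f.rss,
            "ci68_mM": [f.ci_low, f.ci_high],
            "n_boot": f.n_boot,
            "seed": f.seed,
            "well_determined": f.well_determined,
        }
        for rid, f in fits.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_ground_truth(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# plots (vector output)
def plot_titration(series: TitrationSeries, fits: dict[str, FitResult], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    conc = np.asarray(series.concentrations)
    cgrid = np.linspace(0, max(conc) * 1.05, 200)
    for rid in sorted(fits):
        y = series.counts[rid]
        f = fits[rid]
        (pts,) = ax.plot(conc, y, "o", label=f"{rid} (K_D={f.kd_app:.0f} mM)")
        ax.plot(cgrid, f.h_max * cgrid / (cgrid + f.kd_app), "-",
                color=pts.get_color(), alpha=0.7)
    ax.set_xlabel("[Na$^+$] (mM)")
    ax.set_ylabel("corrected peak-to-trough contour levels")
    ax.set_title(f"Na$^+$ titration, pH {series.ph:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_difference_matrix(replicate, path) -> None:
    """Contoured difference maps of one titration ladder, control first."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("control", replicate.control)] + [
        (f"{c.na_mM:g} mM", c.diff) for c in replicate.conditions if c.na_mM > 0
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3.6))
    step = replicate.control.contour_step
    nlev = 12
    levels = [i * step for i in range(1, nlev + 1)]
    for ax, (title, diff) in zip(np.atleast_1d(axes), panels):
        ext = [0, diff.cell.a, 0, diff.cell.b]
        ax.contour(diff.grid.T, levels=levels, colors="tab:blue",
                   linewidths=0.5, extent=ext, origin="lower")
        ax.contour(diff.grid.T, levels=[-l for l in levels[::-1]],
                   colors="tab:red", linewidths=0.5, extent=ext, origin="lower")
        ax.set_title(title, fontsize=9)
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(f"difference maps vs 0 mM, pH {replicate.ph:g} "
                 f"(contours every 1.5σ of control)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
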