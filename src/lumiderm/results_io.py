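"""Result serialisation: CSV artifact files plus a checksummed run manifest.

Machine-readable CSVs carry 17 significant digits so that re-reading
reproduces the in-memory arrays exactly.  Every output directory gets a
``manifest.json`` listing the configuration snapshot, seeds, software
version and a SHA-256 checksum per file; the manifest is sufficient to
re-run the simulation bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mc import SimResult
from .pipeline import SpectralResult, estimate_electric_power

__all__ = ["write_results", "read_summary", "verify_manifest", "ManifestError"]

_FLOAT_FMT = "%.17g"


class ManifestError(RuntimeError):
    """Raised when a manifest check fails (missing file or bad checksum)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _summary_frame(summary: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"quantity": list(summary.keys()), "value": list(summary.values())}
    )


def _long_grid(values: np.ndarray, dr: float, dz: float) -> pd.DataFrame:
    """Long-format (ir, iz, r_mm, z_mm, value) frame; all-zero rows dropped."""
    ir, iz = np.nonzero(values)
    return pd.DataFrame(
        {
            "ir": ir,
            "iz": iz,
            "r_mm": (ir + 0.5) * dr,
            "z_mm": (iz + 0.5) * dz,
            "value": values[ir, iz],
        }
    )


def _write_single(result: SimResult, out_dir: Path) -> list[Path]:
    files = []
    summary = dict(result.summary())
    summary["budget_closure"] = result.budget_closure
    summary["mc_se_diffuse_reflectance"] = result.mc_standard_error(result.diffuse_reflectance)
    path = out_dir / "summary.csv"
    _write_csv(_summary_frame(summary), path)
    files.append(path)

    grid = result.grid
    path = out_dir / "absorption_rz.csv"
    _write_csv(
        _long_grid(grid.absorption[: grid.nr, : grid.nz] / result.n_photons, grid.dr_mm, grid.dz_mm),
        path,
    )
    files.append(path)

    path = out_dir / "reflectance_r.csv"
    _write_csv(
        pd.DataFrame(
            {
                "ir": np.arange(grid.nr),
                "r_mm": (np.arange(grid.nr) + 0.5) * grid.dr_mm,
                "reflectance": grid.reflectance_diffuse[: grid.nr] / result.n_photons,
            }
        ),
        path,
    )
    files.append(path)

    path = out_dir / "crossing_z.csv"
    _write_csv(
        pd.DataFrame(
            {
                "z_mm": result.plane_depths_mm,
                "energy_J": result.crossing_energy_J(),
            }
        ),
        path,
    )
    files.append(path)
    return files


def _write_spectral(result: SpectralResult, out_dir: Path) -> list[Path]:
    files = []
    path = out_dir / "summary.csv"
    _write_csv(_summary_frame(result.summary()), path)
    files.append(path)

    grid = result.grid_ref
    path = out_dir / "combined_energy_rz.csv"
    _write_csv(
        _long_grid(result.combined_energy_density_areal(), grid.dr_mm, grid.dz_mm), path
    )
    files.append(path)

    path = out_dir / "energy_vs_depth.csv"
    _write_csv(
        pd.DataFrame(
            {"z_mm": result.plane_depths_mm, "energy_J": result.combined_crossing_energy_J()}
        ),
        path,
    )
    files.append(path)

    # capture report at the layer boundaries for d/4 and d/2 detectors
    beam_d = 2.0 * result.per_wavelength[0].settings.beam_radius_mm
    depths = [float(b) for b in result.stack.boundaries_mm[1:-1]]
    rows = []
    for depth in depths:
        for radius in (beam_d / 4.0, beam_d / 2.0):
            frac = result.captured_fraction(radius, depth)
            power_opt = result.energy_at_depth(depth) * frac  # J per J-second scale
            lo, hi = estimate_electric_power(power_opt * 1000.0, 0.10, 0.20)
            rows.append(
                {
                    "depth_mm": depth,
                    "detector_radius_mm": radius,
                    "captured_fraction": frac,
                    "electric_mW_low": lo,
                    "electric_mW_high": hi,
                }
            )
    path = out_dir / "capture_report.csv"
    _write_csv(pd.DataFrame(rows), path)
    files.append(path)

    for run in result.per_wavelength:
        sub = out_dir / f"wavelength_{int(run.wavelength_nm)}"
        sub.mkdir(exist_ok=True)
        files.extend(_write_single(run, sub))
    return files


def write_results(result: SimResult | SpectralResult, out_dir: str | Path) -> Path:
    """Write all artifact CSVs plus ``manifest.json``; returns the manifest path."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if isinstance(result, SpectralResult):
            files = _write_spectral(result, out_dir)
            seeds = {
                int(r.wavelength_nm): r.settings.seed for r in result.per_wavelength
            }
            settings = result.per_wavelength[0].settings.to_dict()
        else:
            files = _write_single(result, out_dir)
            seeds = {int(result.wavelength_nm): result.settings.seed}
            settings = result.settings.to_dict()
        manifest = {
            "version": __version__,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "settings": settings,
            "child_seeds": seeds,
            "files": {
                str(p.relative_to(out_dir)): _sha256(p) for p in files
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest_path
    except OSError as exc:
        raise OSError(f"failed writing results under {out_dir}: {exc}") from exc


def read_summary(out_dir: str | Path) -> dict:
    """Read ``summary.csv`` back into a quantity -> value mapping."""
    df = pd.read_csv(Path(out_dir) / "summary.csv")
    return dict(zip(df["quantity"], df["value"]))


def verify_manifest(out_dir: str | Path) -> None:
    """Check every file listed in the manifest exists with a matching checksum."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for rel, expected in manifest["files"].items():
        path = out_dir / rel
        if not path.exists():
            raise ManifestError(f"{path}: listed in manifest but missing")
        actual = _sha256(path)
        if actual != expected:
            raise ManifestError(
                f"{path}: checksum mismatch (expected {expected[:12]}..., got {actual[:12]}...)"
            )
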