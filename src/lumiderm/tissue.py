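"""Layered skin-tissue model and wavelength-resolved optical-property lookup.

The tissue is a stack of plane-parallel, laterally infinite slabs (epidermis,
dermis, fat, muscle by default).  Each layer carries a table of optical
properties indexed by wavelength: absorption coefficient ``mu_a`` and
scattering coefficient ``mu_s`` (both in cm^-1, as conventionally tabulated),
Henyey-Greenstein anisotropy ``g`` and refractive index ``n``.  Lengths are
stored in mm; transport code converts coefficients to mm^-1 once per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "Layer",
    "TissueStack",
    "default_skin_stack",
    "properties_at",
    "layer_of_depth",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Single-wavelength optical properties of one tissue layer.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s : float
        Scattering coefficient, cm^-1.
    g : float
        Anisotropy factor (mean scattering cosine), in [-1, 1].
    n : float
        Refractive index (relative to vacuum), >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must be in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-interaction survival probability mu_s / mu_t."""
        return self.mu_s / self.mu_t


@dataclass(frozen=True)
class Layer:
    """One tissue slab: thickness plus wavelength-indexed optical properties.

    ``wavelength_independent`` marks layers (such as the epidermis here) whose
    properties vary so little over the simulated band that a single row is
    used for every wavelength.
    """

    name: str
    thickness_mm: float
    properties_by_wavelength: dict[float, OpticalProperties]
    wavelength_independent: bool = False

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not self.properties_by_wavelength:
            raise ValueError(f"layer {self.name!r}: needs at least one property row")
        if self.wavelength_independent and len(self.properties_by_wavelength) != 1:
            raise ValueError(
                f"layer {self.name!r}: wavelength-independent layers carry exactly one row"
            )

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.properties_by_wavelength)

    def properties_at(self, wavelength_nm: float) -> OpticalProperties:
        """Look up (or linearly interpolate) properties at ``wavelength_nm``.

        Exact tabulated wavelengths return the row verbatim.  Intermediate
        wavelengths are linearly interpolated field-by-field between the two
        bracketing rows.  Wavelengths outside the tabulated range raise.
        """
        if self.wavelength_independent:
            return next(iter(self.properties_by_wavelength.values()))
        if wavelength_nm in self.properties_by_wavelength:
            return self.properties_by_wavelength[wavelength_nm]
        wls = self.wavelengths
        if not wls[0] <= wavelength_nm <= wls[-1]:
            raise ValueError(
                f"layer {self.name!r}: wavelength {wavelength_nm} nm outside "
                f"tabulated range [{wls[0]}, {wls[-1]}] nm"
            )
        hi_idx = int(np.searchsorted(wls, wavelength_nm))
        lo, hi = wls[hi_idx - 1], wls[hi_idx]
        t = (wavelength_nm - lo) / (hi - lo)
        a, b = self.properties_by_wavelength[lo], self.properties_by_wavelength[hi]
        return OpticalProperties(
            mu_a=a.mu_a + t * (b.mu_a - a.mu_a),
            mu_s=a.mu_s + t * (b.mu_s - a.mu_s),
            g=a.g + t * (b.g - a.g),
            n=a.n + t * (b.n - a.n),
        )


@dataclass(frozen=True)
class TissueStack:
    """Ordered stack of layers, top (z = 0) to bottom, with ambient media.

    ``n_above`` is the refractive index of the medium above the tissue
    (air, 1.0).  ``n_below`` defaults to the last layer's index, i.e. a
    matched (non-reflecting) lower boundary.
    """

    layers: tuple[Layer, ...]
    n_above: float = 1.0
    n_below: float | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if self.n_above < 1.0:
            raise ValueError("n_above must be >= 1")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Depths of the n_layers + 1 layer boundaries; boundary 0 is z = 0."""
        return np.concatenate([[0.0], np.cumsum([l.thickness_mm for l in self.layers])])

    @property
    def total_thickness_mm(self) -> float:
        return float(self.boundaries_mm[-1])

    def n_below_effective(self, wavelength_nm: float) -> float:
        if self.n_below is not None:
            return self.n_below
        return self.layers[-1].properties_at(wavelength_nm).n

    def properties_at(self, layer_index: int, wavelength_nm: float) -> OpticalProperties:
        return properties_at(self, layer_index, wavelength_nm)

    def layer_of_depth(self, z_mm: float) -> int:
        return layer_of_depth(self, z_mm)

    def to_dict(self) -> dict:
        """Plain-dict form used by the YAML config round-trip."""
        layers = []
        for layer in self.layers:
            rows = [
                {
                    "wavelength_nm": float(wl),
                    "mu_a_percm": props.mu_a,
                    "mu_s_percm": props.mu_s,
                    "g": props.g,
                    "n": props.n,
                }
                for wl, props in sorted(layer.properties_by_wavelength.items())
            ]
            entry = {
                "name": layer.name,
                "thickness_mm": layer.thickness_mm,
                "properties": rows,
            }
            if layer.wavelength_independent:
                entry["wavelength_independent"] = True
            layers.append(entry)
        out = {"n_above": self.n_above, "layers": layers}
        if self.n_below is not None:
            out["n_below"] = self.n_below
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TissueStack":
        allowed = {"n_above", "n_below", "layers"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"tissue config: unknown keys {sorted(unknown)}")
        layers = []
        for entry in d["layers"]:
            entry_allowed = {"name", "thickness_mm", "properties", "wavelength_independent"}
            unknown = set(entry) - entry_allowed
            if unknown:
                raise ValueError(
                    f"tissue layer {entry.get('name', '?')!r}: unknown keys {sorted(unknown)}"
                )
            rows = {}
            for row in entry["properties"]:
                row_allowed = {"wavelength_nm", "mu_a_percm", "mu_s_percm", "g", "n"}
                unknown = set(row) - row_allowed
                if unknown:
                    raise ValueError(
                        f"tissue layer {entry['name']!r}: unknown property keys {sorted(unknown)}"
                    )
                rows[float(row["wavelength_nm"])] = OpticalProperties(
                    mu_a=float(row["mu_a_percm"]),
                    mu_s=float(row["mu_s_percm"]),
                    g=float(row["g"]),
                    n=float(row["n"]),
                )
            layers.append(
                Layer(
                    name=str(entry["name"]),
                    thickness_mm=float(entry["thickness_mm"]),
                    properties_by_wavelength=rows,
                    wavelength_independent=bool(entry.get("wavelength_independent", False)),
                )
            )
        return cls(
            layers=tuple(layers),
            n_above=float(d.get("n_above", 1.0)),
            n_below=float(d["n_below"]) if "n_below" in d else None,
        )


def properties_at(
    stack: TissueStack, layer_index: int, wavelength_nm: float
) -> OpticalProperties:
    """Optical properties of layer ``layer_index`` at ``wavelength_nm``."""
    if not 0 <= layer_index < stack.n_layers:
        raise IndexError(f"layer index {layer_index} out of range 0..{stack.n_layers - 1}")
    return stack.layers[layer_index].properties_at(wavelength_nm)


def layer_of_depth(stack: TissueStack, z_mm: float) -> int:
    """Index of the layer containing depth ``z_mm``.

    Layer ``i`` occupies the half-open interval [boundary_i, boundary_{i+1}).
    """
    if z_mm < 0:
        raise ValueError(f"depth must be >= 0, got {z_mm}")
    bounds = stack.boundaries_mm
    if z_mm >= bounds[-1]:
        raise ValueError(f"depth {z_mm} mm is below the bottom of the stack")
    return int(np.searchsorted(bounds, z_mm, side="right") - 1)


# Optical-property table for the four-layer skin model over 800-900 nm.
# Columns: mu_a (cm^-1), mu_s (cm^-1), g.  Refractive indices per layer.
_DERMIS_ROWS = {
    800.0: (0.127, 19.07, 0.86),
    825.0: (0.121, 18.24, 0.87),
    850.0: (0.122, 17.57, 0.87),
    875.0: (0.122, 16.98, 0.88),
    900.0: (0.134, 16.30, 0.89),
}
_FAT_ROWS = {
    800.0: (0.083, 11.09, 0.64),
    825.0: (0.085, 11.12, 0.63),
    850.0: (0.086, 11.09, 0.62),
    875.0: (0.091, 10.97, 0.60),
    900.0: (0.125, 10.88, 0.59),
}
_MUSCLE_ROWS = {
    800.0: (0.284, 6.60, 0.85),
    825.0: (0.309, 6.78, 0.85),
    850.0: (0.343, 6.60, 0.85),
    875.0: (0.368, 6.43, 0.85),
    900.0: (0.393, 6.32, 0.85),
}


def _rows(table: dict, n: float) -> dict[float, OpticalProperties]:
    return {
        wl: OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)
        for wl, (mu_a, mu_s, g) in table.items()
    }


def default_skin_stack() -> TissueStack:
    """The default four-layer skin stack (epidermis / dermis / fat / muscle).

    Epidermis properties are treated as wavelength-independent over
    800-900 nm; the muscle layer is effectively semi-infinite (1e8 mm) so
    photons never reach the lower boundary.  Air (n = 1.0) sits above the
    stack; the lower boundary is index-matched to muscle.
    """
    epidermis = Layer(
        name="epidermis",
        thickness_mm=0.065,
        properties_by_wavelength={850.0: OpticalProperties(55.0, 450.0, 0.8, 1.34)},
        wavelength_independent=True,
    )
    dermis = Layer("dermis", 1.25, _rows(_DERMIS_ROWS, 1.55))
    fat = Layer("fat", 12.0, _rows(_FAT_ROWS, 1.45))
    muscle = Layer("muscle", 1.0e8, _rows(_MUSCLE_ROWS, 1.37))
    return TissueStack(layers=(epidermis, dermis, fat, muscle), n_above=1.0)
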