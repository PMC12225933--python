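"""Hertzian analysis of spherical-probe nanoindentation curves.

The skin-surface stiffness of the embryonic head is measured by indenting a
spherical probe (tip radius ~99 um) to small depth (~2 um) and recording the
load-displacement curve.  In the Hertz small-contact regime the load is

    F = (4/3) * E_eff * sqrt(R) * delta^(3/2)

where ``E_eff`` is the effective Young's modulus reported by the instrument
(no ``1 - nu^2`` correction is applied here; divide by ``1 - nu^2`` to convert
to a sample modulus under the usual rigid-probe assumption).  Fitting is a
linear least-squares problem in ``E_eff`` after the ``delta^(3/2)`` transform;
curves whose fit quality (R^2) falls below a retention threshold (default
0.95, inclusive) are discarded before aggregation, and retained moduli are
summarised as mean +/- SD per biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config

_UM = 1e-6   # metres per micron
_UN = 1e-6   # newtons per micronewton


@dataclass
class IndentationCurve:
    """A load-displacement record for one indentation.

    ``displacement`` is in microns, strictly increasing from 0;
    ``force`` in micronewtons with ``force[0] == 0``; ``probe_radius`` in
    microns.  ``truth_modulus`` (Pa) is set for synthetic curves.
    """

    displacement: np.ndarray
    force: np.ndarray
    probe_radius: float
    truth_modulus: float | None = None
    curve_id: str = ""
    replicate_id: str = ""
    grid_position: tuple[int, int] | None = None
    displacement_unit: str = "um"   # one of um, m
    force_unit: str = "uN"          # one of uN, N

    _LENGTH = {"um": 1.0, "m": 1.0 / _UM}
    _FORCE = {"uN": 1.0, "N": 1.0 / _UN}

    def __post_init__(self):
        # normalise declared units to the canonical um / uN representation,
        # so the fitted modulus is unit-independent
        if self.displacement_unit not in self._LENGTH:
            raise ValueError(f"unknown length unit {self.displacement_unit!r}")
        if self.force_unit not in self._FORCE:
            raise ValueError(f"unknown force unit {self.force_unit!r}")
        scale_l = self._LENGTH[self.displacement_unit]
        scale_f = self._FORCE[self.force_unit]
        self.displacement = np.asarray(self.displacement, dtype=float) * scale_l
        self.force = np.asarray(self.force, dtype=float) * scale_f
        if self.displacement_unit == "m":
            self.probe_radius = self.probe_radius * scale_l
        self.displacement_unit = "um"
        self.force_unit = "uN"
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) and self.displacement[0] != 0.0:
            raise ValueError("displacement must start at 0")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")


@dataclass
class IndentationResult:
    """Fitted effective modulus for one curve."""

    E_eff: float | None        # Pa; None when the fit failed
    fit_quality: float         # R^2 in (-inf, 1]; 0 on failure
    curve_id: str = ""
    replicate_id: str = ""
    grid_position: tuple[int, int] | None = None
    contact_offset: float = 0.0   # um, when offset estimation was enabled
    meta: dict = field(default_factory=dict)


def hertz_force(delta_um, E_eff_pa: float, R_um: float):
    """Hertz spherical-contact load (uN) at depth ``delta_um`` (um).

    Vectorised over ``delta_um``.  Raises for negative depths.
    """
    delta = np.asarray(delta_um, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    f_newton = (4.0 / 3.0) * E_eff_pa * np.sqrt(R_um * _UM) * (delta * _UM) ** 1.5
    return f_newton / _UN


def _hertz_design(delta_um, R_um):
    """The Hertz regressor x(delta) such that F_uN = E_eff * x."""
    return (4.0 / 3.0) * np.sqrt(R_um * _UM) * (np.asarray(delta_um) * _UM) ** 1.5 / _UN


def fit_hertz(
    curve: IndentationCurve,
    estimate_offset: bool = False,
    max_offset_fraction: float = 0.25,
) -> IndentationResult:
    """Least-squares Hertz fit of the effective Young's modulus.

    The model is linear in ``E_eff`` after the ``delta^(3/2)`` transform, so
    the estimate is the closed-form projection ``sum(F x) / sum(x^2)``.  With
    ``estimate_offset=True`` a contact-point shift ``delta0`` is additionally
    profiled over a coarse grid (the instrument's contact detection is not
    modelled otherwise).
    """
    if len(curve.displacement) < 10:
        raise ValueError("need at least 10 samples to fit")
    if np.any(np.diff(curve.displacement) <= 0):
        raise ValueError("displacement must be strictly increasing")

    f = curve.force

    def fit_at_offset(d0: float):
        d = np.clip(curve.displacement - d0, 0.0, None)
        x = _hertz_design(d, curve.probe_radius)
        denom = float(x @ x)
        if denom == 0.0:
            return None, 0.0
        e = float(x @ f) / denom
        resid = f - e * x
        ss_tot = float(((f - f.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        return e, r2

    offsets = [0.0]
    if estimate_offset:
        dmax = curve.displacement[-1]
        offsets = np.linspace(0.0, max_offset_fraction * dmax, 26)
    best = (None, 0.0, 0.0)
    for d0 in np.atleast_1d(offsets):
        e, r2 = fit_at_offset(float(d0))
        if e is not None and r2 > best[1]:
            best = (e, r2, float(d0))
    e, r2, d0 = best
    if e is None or e <= 0:
        return IndentationResult(
            E_eff=None, fit_quality=0.0, curve_id=curve.curve_id,
            replicate_id=curve.replicate_id, grid_position=curve.grid_position,
        )
    return IndentationResult(
        E_eff=e, fit_quality=r2, curve_id=curve.curve_id,
        replicate_id=curve.replicate_id, grid_position=curve.grid_position,
        contact_offset=d0,
    )


def filter_and_aggregate(
    results: list[IndentationResult],
    min_quality: float = config.FIT_QUALITY_MIN,
    grid: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-replicate summary of retained fits.

    Drops results with ``fit_quality < min_quality`` (the threshold is
    inclusive: quality exactly at the threshold is retained) and reports
    mean, SD and retention count of ``E_eff`` per replicate.  Replicates in
    which no curve survives are flagged ``missing``.
    """
    rows = []
    by_rep: dict[str, list[IndentationResult]] = {}
    for r in results:
        by_rep.setdefault(r.replicate_id, []).append(r)
    for rep, rs in by_rep.items():
        if grid is not None and len(rs) != grid[0] * grid[1]:
            raise ValueError(
                f"replicate {rep!r} has {len(rs)} results, expected "
                f"{grid[0]}x{grid[1]}={grid[0] * grid[1]}"
            )
        kept = [r.E_eff for r in rs
                if r.E_eff is not None and r.fit_quality >= min_quality]
        rows.append({
            "replicate_id": rep,
            "n_total": len(rs),
            "n_retained": len(kept),
            "mean_E_eff": float(np.mean(kept)) if kept else np.nan,
            "sd_E_eff": float(np.std(kept, ddof=1)) if len(kept) > 1
                        else (0.0 if len(kept) == 1 else np.nan),
            "missing": len(kept) == 0,
        })
    return pd.DataFrame(rows)


def plot_replicate_series(summary: pd.DataFrame, ax=None, **kwargs):
    """Mean +/- SD effective modulus per replicate (developmental series)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = summary[~summary["missing"]]
    ax.errorbar(
        range(len(ok)), ok["mean_E_eff"], yerr=ok["sd_E_eff"].fillna(0.0),
        fmt="o", capsize=3, **kwargs,
    )
    ax.set_xticks(range(len(ok)), ok["replicate_id"])
    ax.set_ylabel("effective Young's modulus (Pa)")
    return ax
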