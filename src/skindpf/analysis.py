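"""DPF grids, per-layer pathlength tables, sensitivity maps, Beer–Lambert.

The differential pathlength factor at wavelength λ and source–detector
separation d is DPF(λ, d) = ⟨L⟩ / d, the mean total optical pathlength of
detected packets divided by the separation.  Two estimators of ⟨L⟩ are
provided:

* ``weighted`` — Σ wᵢLᵢ / Σ wᵢ over detected packets, the estimator
  consistent with packet weighting (default for general use);
* ``unweighted`` — the plain mean of registered pathlengths, the estimator
  matching free paths drawn from the scattering coefficient alone, so that
  absorption does not shape the path statistics.

Replicate sweeps run N independently seeded transports per wavelength (one
run fills all detector rings at once) and report across-replicate means and
sample standard deviations (ddof = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transport import (
    DetectionLedger,
    InsufficientStatisticsError,
    RunConfig,
    default_ring_edges,
    replicate_seed,
    run_transport,
)

__all__ = [
    "DPFGrid",
    "dpf_from_ledger",
    "replicate_sweep",
    "mbll_attenuation",
    "sensitivity_map",
    "penetration_depth",
    "write_dpf_table",
    "write_dpf_long",
    "write_layer_paths",
]


def dpf_from_ledger(
    ledger: DetectionLedger, sds: float, weighted: bool = True
) -> float:
    """DPF for the detector ring containing the separation ``sds`` (mm).

    Raises :class:`InsufficientStatisticsError` if that ring is empty.
    """
    if sds <= 0:
        raise ValueError("source–detector separation must be > 0")
    ring = int(np.searchsorted(ledger.ring_edges, sds, side="right")) - 1
    if ring < 0 or ring >= ledger.n_rings:
        raise ValueError(f"sds {sds} mm lies outside the detector rings")
    return ledger.mean_path(ring, weighted=weighted) / sds


def mbll_attenuation(
    epsilon: float, concentration: float, d: float, dpf: float
) -> float:
    """Modified Beer–Lambert attenuation A = ε · C · d · DPF."""
    for name, v in (
        ("epsilon", epsilon),
        ("concentration", concentration),
        ("d", d),
        ("dpf", dpf),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return epsilon * concentration * d * dpf


@dataclass
class DPFGrid:
    """Wavelength × separation DPF statistics over replicate runs.

    ``dpf_mean``/``dpf_sd`` have shape (n_wavelengths, n_sds); the sample
    standard deviation is over replicates (ddof = 1) and is all-zero (and
    ``sd_valid`` False) when only one replicate was run.
    ``mean_path_by_layer`` has shape (n_wavelengths, n_sds, n_layers), in mm.
    """

    wavelengths: np.ndarray
    sds: np.ndarray
    dpf_mean: np.ndarray
    dpf_sd: np.ndarray
    dpf_se: np.ndarray  # Monte Carlo SE of the pooled mean, from detection stats
    n_replicates: int
    mean_path_by_layer: np.ndarray
    layer_names: tuple
    weighted: bool

    @property
    def sd_valid(self) -> bool:
        return self.n_replicates > 1

    def dpf(self, wavelength: float, sds: float) -> float:
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        j = int(np.argmin(np.abs(self.sds - sds)))
        if abs(self.wavelengths[i] - wavelength) > 0.5 or abs(self.sds[j] - sds) > 1e-9:
            raise ValueError(f"({wavelength} nm, {sds} mm) not in this grid")
        return float(self.dpf_mean[i, j])

    def total_mean_path(self) -> np.ndarray:
        """Mean total pathlength (mm) per cell = DPF × separation."""
        return self.dpf_mean * self.sds[None, :]


def replicate_sweep(
    model,
    wavelengths,
    sds,
    n_photons: int,
    n_replicates: int = 20,
    base_seed: int = 0,
    *,
    config_template: RunConfig | None = None,
    ring_width: float = 0.5,
    weighted: bool = True,
    progress=None,
) -> DPFGrid:
    """Replicated transport sweep over wavelengths, all separations at once.

    Parameters
    ----------
    model : SkinModel
    wavelengths, sds
        Wavelength list (nm) and strictly increasing separation list (mm).
    n_photons, n_replicates, base_seed
        Photon budget per replicate; replicate seeds derive from
        (base_seed, wavelength index, replicate index) and are independent.
    config_template
        Engine switches to use (photon count/seed/wavelength are overridden).
    weighted
        Estimator for the mean detected pathlength (see module docstring).
    progress
        Optional callable ``progress(message: str)`` for long runs.

    Raises :class:`InsufficientStatisticsError`, with (λ, d, replicate)
    context, if any ring of any replicate receives no packets.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    template = config_template if config_template is not None else RunConfig()
    ring_edges = default_ring_edges(sds, width=ring_width)

    n_l, n_d = len(wavelengths), len(sds)
    dpf_reps = np.zeros((n_l, n_d, n_replicates))
    dpf_se = np.zeros((n_l, n_d))
    layer_sums = np.zeros((n_l, n_d, model.n_layers))
    rings = [int(np.searchsorted(ring_edges, d, side="right")) - 1 for d in sds]

    for i, wl in enumerate(wavelengths):
        pooled = None
        for rep in range(n_replicates):
            cfg = RunConfig(
                n_photons=n_photons,
                seed=replicate_seed(base_seed, i * 10_000 + rep),
                wavelength=float(wl),
                step_sampling_mode=template.step_sampling_mode,
                roulette_threshold=template.roulette_threshold,
                roulette_survival=template.roulette_survival,
                max_path=template.max_path,
                matched_boundaries=template.matched_boundaries,
                extend_bottom=template.extend_bottom,
                chunk_size=template.chunk_size,
            )
            ledger = run_transport(model, cfg, ring_edges)
            if pooled is None:
                pooled = ledger
            else:
                pooled.merge(ledger)
            for j, d in enumerate(sds):
                try:
                    dpf_reps[i, j, rep] = dpf_from_ledger(ledger, d, weighted=weighted)
                    layer_sums[i, j] += ledger.mean_path_by_layer(
                        rings[j], weighted=weighted
                    )
                except InsufficientStatisticsError as exc:
                    raise InsufficientStatisticsError(
                        f"{exc} (wavelength {wl:g} nm, sds {d:g} mm, "
                        f"replicate {rep})"
                    ) from None
            if progress is not None:
                progress(
                    f"λ={wl:g} nm replicate {rep + 1}/{n_replicates}: "
                    f"detected {int(ledger.n_detected.sum())} packets in rings, "
                    f"residual {ledger.conservation_residual():.2e}"
                )

        for j, d in enumerate(sds):
            dpf_se[i, j] = pooled.mean_path_se(rings[j], weighted=weighted) / d

    dpf_mean = dpf_reps.mean(axis=2)
    dpf_sd = (
        dpf_reps.std(axis=2, ddof=1) if n_replicates > 1 else np.zeros((n_l, n_d))
    )
    return DPFGrid(
        wavelengths=wavelengths,
        sds=sds,
        dpf_mean=dpf_mean,
        dpf_sd=dpf_sd,
        dpf_se=dpf_se,
        n_replicates=n_replicates,
        mean_path_by_layer=layer_sums / n_replicates,
        layer_names=tuple(l.name for l in model.layers),
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# Spatial sensitivity ("banana") maps
# ---------------------------------------------------------------------------

def sensitivity_map(
    model,
    config: RunConfig,
    sds: float,
    *,
    ring_width: float = 0.5,
    x_edges=None,
    z_edges=None,
):
    """Weight-scaled visit map of detected packets in the x–z plane.

    For every packet detected in the annulus centred on ``sds``, the
    pathlength spent in each spatial bin, scaled by the detected weight, is
    accumulated; each trajectory is first rotated about the z axis so its
    exit lands at azimuth zero (+x toward the detector), exploiting the
    model's radial symmetry.  The map is normalised to sum to 1.

    Returns ``(map, x_edges, z_edges)``.
    """
    from ._sensmap import trace_sensitivity  # deferred: compiles on first use

    if x_edges is None:
        x_edges = np.linspace(-2.0, sds + 2.0, 121)
    if z_edges is None:
        z_edges = np.linspace(0.0, model.total_thickness, 60)
    x_edges = np.ascontiguousarray(x_edges, dtype=float)
    z_edges = np.ascontiguousarray(z_edges, dtype=float)
    half = ring_width / 2.0
    r_lo, r_hi = max(sds - half, 0.0), sds + half

    z_top, z_bot, mua, mus, g_arr, n_arr = model.optical_arrays(config.wavelength)
    grid, n_det = trace_sensitivity(
        config.n_photons,
        config.seed,
        z_top,
        z_bot,
        mua,
        mus,
        g_arr,
        n_arr,
        model.n_ambient,
        config.step_sampling_mode == "total",
        not config.matched_boundaries,
        config.extend_bottom,
        config.roulette_threshold,
        config.roulette_survival,
        config.max_path,
        r_lo,
        r_hi,
        x_edges,
        z_edges,
    )
    if n_det == 0:
        raise InsufficientStatisticsError(
            f"no packets detected in the {r_lo:.2f}–{r_hi:.2f} mm annulus"
        )
    total = grid.sum()
    if total <= 0:
        raise InsufficientStatisticsError("empty sensitivity accumulation")
    return grid / total, x_edges, z_edges


def penetration_depth(grid: np.ndarray, z_edges: np.ndarray) -> float:
    """Depth (mm) of the maximum of the depth-marginal sensitivity profile."""
    profile = grid.sum(axis=0)  # grid is (x, z)
    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    return float(centers[int(np.argmax(profile))])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dpf_table(grid: DPFGrid, path) -> None:
    """Wide CSV: rows = SDS (mm), one DPF column per wavelength."""
    df = pd.DataFrame(
        grid.dpf_mean.T,
        index=pd.Index(grid.sds, name="SDS (mm)"),
        columns=[f"DPF{int(wl)}nm" for wl in grid.wavelengths],
    )
    df.to_csv(path)


def write_dpf_long(grid: DPFGrid, path) -> None:
    """Long CSV with one row per (wavelength, SDS): mean, sd, n_replicates."""
    rows = []
    for i, wl in enumerate(grid.wavelengths):
        for j, d in enumerate(grid.sds):
            rows.append(
                {
                    "wavelength_nm": wl,
                    "sds_mm": d,
                    "dpf_mean": grid.dpf_mean[i, j],
                    "dpf_sd": grid.dpf_sd[i, j],
                    "n_replicates": grid.n_replicates,
                    "estimator": "weighted" if grid.weighted else "unweighted",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_layer_paths(grid: DPFGrid, path) -> None:
    """Long CSV of per-layer mean partial pathlengths (mm)."""
    rows = []
    for i, wl in enumerate(grid.wavelengths):
        for j, d in enumerate(grid.sds):
            for k, name in enumerate(grid.layer_names):
                rows.append(
                    {
                        "wavelength_nm": wl,
                        "sds_mm": d,
                        "layer": name,
                        "mean_path_mm": grid.mean_path_by_layer[i, j, k],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, **entries) -> None:
    """JSON manifest capturing the exact configuration of a run."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
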