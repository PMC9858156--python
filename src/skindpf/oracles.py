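"""Deliberately simple reference implementations used for cross-checks.

Nothing here imports or reuses the compiled engine: the scalar walker is an
independent, one-photon-at-a-time Python re-derivation of the same physics,
the diffusion DPF is the steady-state closed form for a homogeneous
semi-infinite medium, and the Henyey–Greenstein moments come from numerical
quadrature of the phase-function density.  These are test oracles, not
production code paths.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from scipy.integrate import quad

__all__ = [
    "OracleResult",
    "scalar_walker",
    "diffusion_dpf",
    "hg_mean_cos",
]


@dataclass
class OracleResult:
    """Point estimate with its standard error and a method tag."""

    estimate: float
    standard_error: float
    method: str
    n_detected: int = 0

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard_error must be >= 0")


def diffusion_dpf(mua: float, mus_reduced: float, d: float) -> float:
    """Steady-state diffusion-theory DPF for a semi-infinite medium.

    DPF = (1/2)·√(3μs′/μa)·[1 − 1/(1 + d·√(3 μa μs′))].

    Valid for μs′ ≫ μa and separations of several transport mean free paths.
    """
    if mua <= 0 or mus_reduced <= 0 or d <= 0:
        raise ValueError("mua, mus_reduced and d must all be > 0")
    return 0.5 * math.sqrt(3.0 * mus_reduced / mua) * (
        1.0 - 1.0 / (1.0 + d * math.sqrt(3.0 * mua * mus_reduced))
    )


def hg_mean_cos(g: float) -> float:
    """⟨cosθ⟩ of the Henyey–Greenstein density by numerical quadrature."""
    if not abs(g) < 1.0:
        raise ValueError("|g| must be < 1")
    if abs(g) < 1e-12:
        return 0.0

    def pdf(mu):
        return 0.5 * (1 - g * g) / (1 + g * g - 2 * g * mu) ** 1.5

    num, _ = quad(lambda mu: mu * pdf(mu), -1, 1)
    den, _ = quad(pdf, -1, 1)
    return num / den


def _walker_fresnel(cos_i, n1, n2):
    if n1 == n2:
        return 0.0, 1.0
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i**2)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp), cos_t


def scalar_walker(
    model,
    config,
    ring_edges,
    weighted: bool = True,
) -> list[OracleResult]:
    """One-photon-at-a-time random walk; returns mean detected path per ring.

    Implements the identical physics contract as the main engine — pencil
    source, exponential steps (μt or μs per ``config.step_sampling_mode``),
    per-interaction weight deposit μa/(μa+μs), Henyey–Greenstein scattering,
    Fresnel boundaries, optional roulette — written independently and
    without vectorisation.  Intended for photon budgets ≤ 1e5.
    """
    rng = random.Random(config.seed)
    boundaries = model.boundaries()
    mua = model.mua(config.wavelength)
    mus = model.mus(config.wavelength)
    gs = [l.g for l in model.layers]
    ns = [l.n for l in model.layers]
    n_layers = len(model.layers)
    use_total = config.step_sampling_mode == "total"
    fresnel_on = not config.matched_boundaries

    n_rings = len(ring_edges) - 1
    paths = [[] for _ in range(n_rings)]
    weights = [[] for _ in range(n_rings)]

    if fresnel_on:
        r_sp, _ = _walker_fresnel(1.0, model.n_ambient, ns[0])
    else:
        r_sp = 0.0

    for _ in range(config.n_photons):
        x = y = z = 0.0
        ux = uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0 - r_sp
        path = 0.0
        alive = True

        while alive:
            s = -math.log(1.0 - rng.random())
            while True:
                mu_samp = (mua[layer] + mus[layer]) if use_total else mus[layer]
                step = s / mu_samp
                if uz > 0.0:
                    if config.extend_bottom and layer == n_layers - 1:
                        db = float("inf")
                    else:
                        db = (boundaries[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (boundaries[layer] - z) / uz
                else:
                    db = float("inf")
                if step < db:
                    x += step * ux
                    y += step * uy
                    z += step * uz
                    path += step
                    break
                x += db * ux
                y += db * uy
                path += db
                s -= db * mu_samp
                if path > config.max_path:
                    alive = False
                    break
                going_up = uz < 0.0
                if going_up:
                    z = boundaries[layer]
                    if layer == 0:
                        refl, cos_t = (
                            _walker_fresnel(-uz, ns[0], model.n_ambient)
                            if fresnel_on
                            else (0.0, 1.0)
                        )
                        if refl < 1.0 and rng.random() >= refl:
                            r = math.hypot(x, y)
                            for k in range(n_rings):
                                if ring_edges[k] <= r < ring_edges[k + 1]:
                                    paths[k].append(path)
                                    weights[k].append(w)
                                    break
                            alive = False
                            break
                        uz = -uz
                    else:
                        n1, n2 = ns[layer], ns[layer - 1]
                        if fresnel_on and n1 != n2:
                            refl, cos_t = _walker_fresnel(-uz, n1, n2)
                            if rng.random() < refl:
                                uz = -uz
                            else:
                                ratio = n1 / n2
                                ux *= ratio
                                uy *= ratio
                                uz = -cos_t
                                layer -= 1
                        else:
                            layer -= 1
                else:
                    z = boundaries[layer + 1]
                    if layer == n_layers - 1:
                        alive = False
                        break
                    n1, n2 = ns[layer], ns[layer + 1]
                    if fresnel_on and n1 != n2:
                        refl, cos_t = _walker_fresnel(uz, n1, n2)
                        if rng.random() < refl:
                            uz = -uz
                        else:
                            ratio = n1 / n2
                            ux *= ratio
                            uy *= ratio
                            uz = cos_t
                            layer += 1
                    else:
                        layer += 1
            if not alive:
                break
            if path > config.max_path:
                break

            w -= w * mua[layer] / (mua[layer] + mus[layer])
            g = gs[layer]
            u = rng.random()
            if abs(g) < 1e-8:
                cost = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = max(-1.0, min(1.0, (1.0 + g * g - tmp * tmp) / (2.0 * g)))
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * rng.random()
            if abs(uz) > 0.99999:
                ux_n = sint * math.cos(phi)
                uy_n = sint * math.sin(phi)
                uz_n = cost if uz > 0 else -cost
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = sint * (ux * uz * math.cos(phi) - uy * math.sin(phi)) / den + ux * cost
                uy_n = sint * (uy * uz * math.cos(phi) + ux * math.sin(phi)) / den + uy * cost
                uz_n = -sint * math.cos(phi) * den + uz * cost
            norm = math.sqrt(ux_n**2 + uy_n**2 + uz_n**2)
            ux, uy, uz = ux_n / norm, uy_n / norm, uz_n / norm
            if config.roulette_threshold > 0.0 and w < config.roulette_threshold:
                if rng.random() < config.roulette_survival:
                    w /= config.roulette_survival
                else:
                    break

    results = []
    for k in range(n_rings):
        n = len(paths[k])
        if n == 0:
            results.append(OracleResult(math.nan, 0.0, "scalar_walker", 0))
            continue
        if weighted:
            wsum = sum(weights[k])
            mean = sum(wi * li for wi, li in zip(weights[k], paths[k])) / wsum
            # weighted SE via effective sample size
            neff = wsum**2 / sum(wi * wi for wi in weights[k])
            var = (
                sum(wi * (li - mean) ** 2 for wi, li in zip(weights[k], paths[k]))
                / wsum
            )
            se = math.sqrt(var / max(neff, 1.0))
        else:
            mean = sum(paths[k]) / n
            var = sum((li - mean) ** 2 for li in paths[k]) / max(n - 1, 1)
            se = math.sqrt(var / n)
        results.append(OracleResult(mean, se, "scalar_walker", n))
    return results
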