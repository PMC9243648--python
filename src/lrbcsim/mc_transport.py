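"""Weighted-packet Monte Carlo photon transport in layered tissue.

Standard multilayer conventions: photon packets launched at the origin
with normal incidence lose the specular fraction at entry, then execute
hop/drop/spin cycles — exponential step sampling with dimensionless-
pathlength bookkeeping across layer boundaries, fractional absorption
``dW = W * mua/mut`` at each interaction, Henyey-Greenstein scattering —
with unpolarized Fresnel reflection/refraction at every refractive-index
mismatch and Russian-roulette termination of low-weight packets.
Cylindrical symmetry about the entry axis; packets exiting through the
top surface are tallied by radial exit distance.

The kernel is compiled with numba and is fully deterministic given the
seed: one seed, one bit-identical tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .skin_model import SkinModel


@dataclass(frozen=True)
class TransportConfig:
    """Monte Carlo run parameters.

    ``n_packets`` incident photon packets are launched per run.  Packets
    whose weight falls below ``roulette_threshold`` survive roulette with
    probability ``1/roulette_survival`` (weight multiplied by the survival
    factor, conserving expectation).  The radial tally uses bins of width
    ``bin_width`` centered at integer multiples of the width (edges at
    ``bin_width/2 + k*bin_width``); exits beyond ``max_radius`` land in an
    overflow bin.
    """

    n_packets: int = 100_000
    seed: int = 12345
    roulette_threshold: float = 1e-4
    roulette_survival: int = 10
    max_radius: float = 5.0
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette_threshold must be in (0, 1)")
        if self.roulette_survival < 2:
            raise ValueError("roulette_survival must be >= 2")
        if self.max_radius <= 0 or self.bin_width <= 0:
            raise ValueError("max_radius and bin_width must be positive")


@dataclass
class RadialReflectanceProfile:
    """Diffusely reflected weight per incident packet, per radial annulus.

    ``bin_centers`` are annulus centers in mm; ``bin_values`` the exited
    weight per incident photon in each annulus; ``overflow`` the weight
    beyond the last bin.  ``bin_stderr`` is populated by run averaging.
    """

    bin_centers: np.ndarray
    bin_values: np.ndarray
    n_packets: int
    overflow: float = 0.0
    bin_stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.bin_centers.shape != self.bin_values.shape:
            raise ValueError("bin_centers and bin_values must have equal length")
        if np.any(self.bin_values < -1e-15):
            raise ValueError("bin_values must be nonnegative")


@dataclass
class TransportResult:
    """Tallies of one transport run, all per incident photon.

    ``specular_reflectance + total_diffuse_reflectance +
    total_transmittance + absorbed_fraction + terminated_weight`` equals 1
    exactly (roulette kills and boosts are booked in
    ``terminated_weight``, whose expectation is 0).  Raw exit radii and
    weights are retained so that detector windows can be evaluated
    without binning error.
    """

    specular_reflectance: float
    total_diffuse_reflectance: float
    total_transmittance: float
    absorbed_fraction: float
    terminated_weight: float
    exit_radii: np.ndarray
    exit_weights: np.ndarray
    n_packets: int
    config: TransportConfig
    model: SkinModel

    @property
    def diffuse_reflectance_profile(self) -> RadialReflectanceProfile:
        return bin_profile(self, self.config.bin_width, self.config.max_radius)


def _model_arrays(model: SkinModel):
    nl = len(model.layers)
    d = np.empty(nl)
    mua = np.empty(nl)
    mus = np.empty(nl)
    g = np.empty(nl)
    n = np.empty(nl)
    for i, lay in enumerate(model.layers):
        d[i], mua[i], mus[i], g[i], n[i] = lay.d, lay.mua, lay.mus, lay.g, lay.n
        if lay.mua + lay.mus <= 0:
            raise ValueError(f"layer {lay.name!r}: mua + mus must be positive")
    z_bounds = np.empty(nl + 1)
    z_bounds[0] = 0.0
    np.cumsum(d, out=z_bounds[1:])
    return d, mua, mus, g, n, z_bounds


@njit(cache=True)
def _fresnel(ci: float, ni: float, nt: float):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    ``ci`` is |cos| of the incidence angle.  Returns (R, ct); R = 1 under
    total internal reflection.
    """
    if ni == nt:
        return 0.0, ci
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = ni * si / nt
    if st >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st * st)
    rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
    rp = (ni * ct - nt * ci) / (ni * ct + nt * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True)
def _kernel(d, mua, mus, g, n, z_bounds, n_above, n_below,
            n_packets, seed, w_threshold, m_survival):
    np.random.seed(seed)
    nl = d.shape[0]

    # specular loss at normal-incidence entry
    rsp1 = (n_above - n[0]) / (n_above + n[0])
    rsp = rsp1 * rsp1

    exit_r = np.empty(n_packets)
    exit_w = np.empty(n_packets)
    n_exit = 0
    total_rd = 0.0
    total_t = 0.0
    total_a = 0.0
    terminated = 0.0
    inv_m = 1.0 / m_survival

    for _ in range(n_packets):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        lay = 0
        w = 1.0 - rsp
        alive = True
        while alive:
            sleft = -math.log(np.random.random())  # dimensionless pathlength
            while sleft > 0.0:
                mut = mua[lay] + mus[lay]
                sgeo = sleft / mut
                if uz > 0.0:
                    db = (z_bounds[lay + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[lay] - z) / uz
                else:
                    db = math.inf
                if db < sgeo:
                    # hop to the boundary, bank the unused pathlength
                    x += ux * db
                    y += uy * db
                    sleft -= db * mut
                    going_up = uz < 0.0
                    z = z_bounds[lay] if going_up else z_bounds[lay + 1]
                    if going_up:
                        nt = n_above if lay == 0 else n[lay - 1]
                    else:
                        nt = n_below if lay == nl - 1 else n[lay + 1]
                    ci = abs(uz)
                    refl, ct = _fresnel(ci, n[lay], nt)
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        scale = n[lay] / nt
                        ux *= scale
                        uy *= scale
                        if going_up:
                            if lay == 0:
                                r = math.sqrt(x * x + y * y)
                                exit_r[n_exit] = r
                                exit_w[n_exit] = w
                                n_exit += 1
                                total_rd += w
                                alive = False
                                break
                            lay -= 1
                            uz = -ct
                        else:
                            if lay == nl - 1:
                                total_t += w
                                alive = False
                                break
                            lay += 1
                            uz = ct
                else:
                    x += ux * sgeo
                    y += uy * sgeo
                    z += uz * sgeo
                    sleft = 0.0
                    # drop
                    dw = w * mua[lay] / mut
                    total_a += dw
                    w -= dw
                    # spin (Henyey-Greenstein)
                    gg = g[lay]
                    if gg == 0.0:
                        cost = 2.0 * np.random.random() - 1.0
                    else:
                        tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                        cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                        if cost > 1.0:
                            cost = 1.0
                        elif cost < -1.0:
                            cost = -1.0
                    sint = math.sqrt(1.0 - cost * cost)
                    psi = 2.0 * math.pi * np.random.random()
                    cosp = math.cos(psi)
                    sinp = math.sin(psi)
                    if abs(uz) > 0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        temp = math.sqrt(1.0 - uz * uz)
                        ux_new = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
                        uy_new = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
                        uz_new = -sint * cosp * temp + uz * cost
                        norm = math.sqrt(ux_new * ux_new + uy_new * uy_new + uz_new * uz_new)
                        ux = ux_new / norm
                        uy = uy_new / norm
                        uz = uz_new / norm
                    # roulette (a packet at exactly zero weight dies outright)
                    if w < w_threshold:
                        if w > 0.0 and np.random.random() < inv_m:
                            terminated -= (m_survival - 1.0) * w
                            w *= m_survival
                        else:
                            terminated += w
                            alive = False
                            break
    return (rsp, exit_r[:n_exit].copy(), exit_w[:n_exit].copy(),
            total_rd, total_t, total_a, terminated)


def run_transport(model: SkinModel, config: TransportConfig) -> TransportResult:
    """Run one Monte Carlo transport simulation.

    Deterministic given ``(model, config)`` including the seed.  Returns
    per-incident-photon tallies together with the raw exit radii and
    weights of every diffusely reflected packet.
    """
    d, mua, mus, g, n, z_bounds = _model_arrays(model)
    semi = model.semi_infinite
    if semi:
        z_bounds[-1] = np.inf
    rsp, er, ew, rd, t, a, term = _kernel(
        d, mua, mus, g, n, z_bounds, model.n_above, model.n_above,
        config.n_packets, config.seed, config.roulette_threshold,
        config.roulette_survival,
    )
    n0 = config.n_packets
    return TransportResult(
        specular_reflectance=rsp,
        total_diffuse_reflectance=rd / n0,
        total_transmittance=t / n0,
        absorbed_fraction=a / n0,
        terminated_weight=term / n0,
        exit_radii=er,
        exit_weights=ew / n0,
        n_packets=n0,
        config=config,
        model=model,
    )


def bin_profile(result: TransportResult, bin_width: float = 0.1,
                max_radius: float = 5.0) -> RadialReflectanceProfile:
    """Regroup raw exit radii into annuli of width ``bin_width``.

    Bins are centered at ``bin_width * k`` with edges at ``bin_width/2 +
    bin_width * k``; the innermost bin is the half-annulus [0,
    bin_width/2) centered at r = 0, so every exit radius is counted once.
    Weight beyond ``max_radius`` goes to the overflow tally.
    """
    n_bins = int(round(max_radius / bin_width))
    centers = bin_width * np.arange(0, n_bins + 1)
    edges = np.concatenate(([0.0], bin_width / 2 + bin_width * np.arange(0, n_bins + 1)))
    values, _ = np.histogram(result.exit_radii, bins=edges, weights=result.exit_weights)
    overflow = float(result.exit_weights[result.exit_radii > edges[-1]].sum())
    return RadialReflectanceProfile(bin_centers=centers, bin_values=values,
                                    n_packets=result.n_packets, overflow=overflow)


def annulus_intensity(result: TransportResult, r_min: float, r_max: float) -> float:
    """Exited weight per incident photon with exit radius in [r_min, r_max].

    Computed from the raw exit radii (no binning error).  The default
    detection window of the reflectometer geometry is 0.5-1.2 mm.
    """
    if r_min < 0 or r_min >= r_max:
        raise ValueError("need 0 <= r_min < r_max")
    mask = (result.exit_radii >= r_min) & (result.exit_radii <= r_max)
    return float(result.exit_weights[mask].sum())


def average_runs(model: SkinModel, config: TransportConfig,
                 n_runs: int) -> RadialReflectanceProfile:
    """Average the radial profiles of ``n_runs`` independent runs.

    Per-run seeds are ``config.seed + k`` for run k; the returned profile
    carries the arithmetic mean per bin and the standard error of that
    mean across runs in ``bin_stderr``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    profiles = []
    for k in range(n_runs):
        res = run_transport(model, replace(config, seed=config.seed + k))
        profiles.append(bin_profile(res, config.bin_width, config.max_radius))
    values = np.stack([p.bin_values for p in profiles])
    mean = values.mean(axis=0)
    stderr = (values.std(axis=0, ddof=1) / math.sqrt(n_runs)
              if n_runs > 1 else np.zeros_like(mean))
    return RadialReflectanceProfile(
        bin_centers=profiles[0].bin_centers, bin_values=mean,
        n_packets=config.n_packets * n_runs,
        overflow=float(np.mean([p.overflow for p in profiles])),
        bin_stderr=stderr,
    )
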