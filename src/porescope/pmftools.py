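"""1D free-energy profiles from ion-coordinate samples, and gate barriers.

The permeation observable of interest is the potential of mean force F(z) of a
chloride ion along the pore axis, oriented extracellular → cytoplasmic from
left to right with the −2′ desensitisation gate at z = 0 nm. Adaptive-bias MD
produces such profiles at cluster scale; this module handles only the 1D
post-processing:

- Boltzmann inversion ``F(z) = −k_B·T·ln ρ̂(z)`` of (optionally
  bias-reweighted) coordinate samples, offset so the minimum inside a chosen
  reference window — by convention the bulk-solution flank — is zero, with
  low-count bins masked as gaps rather than reported;
- barrier extraction: max F inside a gate window minus the minimum over the
  sampled flanking regions;
- a reflecting-boundary Metropolis sampler over an arbitrary 1D potential, the
  recovery oracle for the inversion.

Units: nm for z, kJ/mol for energies; k_B·T at the default 300 K is
2.494 kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KB_KJ_PER_MOL_K",
    "PmfProfile",
    "IonSamples",
    "boltzmann_invert",
    "barrier_height",
    "metropolis_sample",
    "double_well",
    "harmonic",
    "gaussian_barrier",
]

KB_KJ_PER_MOL_K = 0.008314462618  # kJ/mol/K
DEFAULT_TEMPERATURE = 300.0       # K; k_B·T = 2.494 kJ/mol
MIN_BIN_COUNT = 5                 # bins with fewer raw counts are masked


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    return KB_KJ_PER_MOL_K * temperature


# ---------------------------------------------------------------------------
# Toy potentials (kJ/mol over z in nm)
# ---------------------------------------------------------------------------

def harmonic(k: float, z0: float = 0.0):
    """U(z) = ½ k (z − z0)²; k in kJ/mol/nm²."""
    return lambda z: 0.5 * k * (z - z0) ** 2


def double_well(barrier: float, half_separation: float = 0.5):
    """Symmetric quartic double well with wells at ±a and barrier height at 0."""
    a = half_separation
    return lambda z: barrier * ((z / a) ** 2 - 1.0) ** 2


def gaussian_barrier(height: float, center: float, width: float = 0.25):
    """Single Gaussian bump of given height (kJ/mol) at ``center`` (nm)."""
    return lambda z: height * np.exp(-0.5 * ((z - center) / width) ** 2)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class IonSamples:
    """Scalar ion-coordinate samples (nm) with optional per-sample bias (kJ/mol)."""

    z: np.ndarray
    bias: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    seed: int | None = None
    acceptance_rate: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite coordinate samples")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != self.z.shape:
                raise ValueError("bias array must match sample array")

    @property
    def n(self) -> int:
        return self.z.size


@dataclass
class PmfProfile:
    """Free-energy curve on uniform bin centres; NaN + mask where unsampled."""

    z_grid: np.ndarray            # nm, bin centres, increasing
    free_energy: np.ndarray       # kJ/mol, NaN in gaps
    gaps: np.ndarray              # bool, True where masked
    reference_window: tuple
    temperature: float

    def sampled(self) -> np.ndarray:
        return ~self.gaps


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def boltzmann_invert(samples: IonSamples, bin_width: float,
                     reference_window: tuple,
                     z_range: tuple | None = None) -> PmfProfile:
    """Invert a sample histogram into F(z) = −k_B·T·ln ρ̂(z).

    When per-sample bias energies are present the histogram is reweighted by
    exp(+bias / k_B·T) (standard umbrella unweighting). Bins with fewer than
    5 raw counts are masked as gaps. The profile is offset so the minimum of F
    inside ``reference_window = (z_lo, z_hi)`` is exactly 0.
    """
    if samples.n < 1000:
        raise ValueError(f"need ≥1000 samples for inversion, got {samples.n}")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    z = samples.z
    lo, hi = (z.min(), z.max()) if z_range is None else z_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    if samples.bias is not None:
        weights = np.exp(samples.bias / kt(samples.temperature))
        hist, _ = np.histogram(z, bins=edges, weights=weights)
    else:
        hist = counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("all samples fall outside the requested z range")
    gaps = counts < MIN_BIN_COUNT
    if gaps.all():
        raise ValueError("histogram empty: every bin has fewer than "
                         f"{MIN_BIN_COUNT} counts")
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full(n_bins, np.nan)
    dens = hist[~gaps] / (hist.sum() * bin_width)
    F[~gaps] = -kt(samples.temperature) * np.log(dens)
    ref_lo, ref_hi = reference_window
    in_ref = (~gaps) & (centers >= ref_lo) & (centers <= ref_hi)
    if not in_ref.any():
        raise ValueError("reference window contains no sampled bins")
    F -= np.nanmin(F[in_ref])
    return PmfProfile(z_grid=centers, free_energy=F, gaps=gaps,
                      reference_window=(float(ref_lo), float(ref_hi)),
                      temperature=samples.temperature)


def barrier_height(profile: PmfProfile, gate_window: tuple):
    """Barrier across a gate: max F inside the window minus the flanking minimum.

    Returns ``(height_kJ_per_mol, z_of_maximum)``. The reference level is the
    lowest sampled free energy outside the window (both flanks pooled); if the
    window itself is a gap, an error is raised.
    """
    lo, hi = gate_window
    ok = profile.sampled()
    in_win = ok & (profile.z_grid >= lo) & (profile.z_grid <= hi)
    if not in_win.any():
        raise ValueError(f"gate window ({lo}, {hi}) nm is unsampled")
    out_win = ok & ~((profile.z_grid >= lo) & (profile.z_grid <= hi))
    base = float(np.nanmin(profile.free_energy[out_win])) if out_win.any() else 0.0
    idx = np.flatnonzero(in_win)
    j = idx[int(np.nanargmax(profile.free_energy[idx]))]
    return (float(profile.free_energy[j] - base), float(profile.z_grid[j]))


def metropolis_sample(potential, n: int, step: float = 0.3,
                      temperature: float = DEFAULT_TEMPERATURE,
                      seed: int = 0, z0: float = 0.0,
                      bounds: tuple = (-1.5, 1.5),
                      burn_in: int = 1000) -> IonSamples:
    """Metropolis chain targeting exp(−U/k_B·T) with reflecting bounds.

    Gaussian proposals of s.d. ``step`` (nm); proposals outside ``bounds`` are
    reflected back inside, mimicking a flat-bottom confinement without
    implementing a restraint. The chain is a pure function of the seed; the
    realised acceptance rate is recorded on the returned samples.
    """
    if n <= 0:
        raise ValueError("sample count must be positive")
    if step <= 0:
        raise ValueError("proposal step must be positive")
    beta = 1.0 / kt(temperature)
    lo, hi = bounds
    width = hi - lo
    u0 = float(potential(z0))
    if not np.isfinite(u0):
        raise ValueError(f"potential is non-finite at start point {z0}")
    rng = np.random.Generator(np.random.PCG64(seed))
    total = n + burn_in
    steps = rng.normal(0.0, step, size=total)
    unif = rng.random(total)
    out = np.empty(total)
    z, u = z0, u0
    two_w = 2.0 * width
    for i in range(total):
        zp = z + steps[i]
        # reflect into [lo, hi]
        y = (zp - lo) % two_w
        if y > width:
            y = two_w - y
        zp = lo + y
        up = float(potential(zp))
        if up <= u or unif[i] < np.exp(-beta * (up - u)):
            z, u = zp, up
        out[i] = z
    accepted = np.count_nonzero(np.diff(out) != 0.0) / max(1, total - 1)
    return IonSamples(z=out[burn_in:], temperature=temperature, seed=seed,
                      acceptance_rate=float(accepted))


def fit_harmonic_curvature(profile: PmfProfile, z0: float = 0.0,
                           half_width: float = 0.25) -> float:
    """Quadratic fit of F(z) around ``z0``; returns curvature k (kJ/mol/nm²)."""
    ok = profile.sampled() & (np.abs(profile.z_grid - z0) <= half_width)
    if ok.sum() < 3:
        raise ValueError("too few sampled bins near the minimum for a fit")
    c = np.polyfit(profile.z_grid[ok] - z0, profile.free_energy[ok], 2)
    return float(2.0 * c[0])
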