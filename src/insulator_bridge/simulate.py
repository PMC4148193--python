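"""Synthetic-data generators for every analysis stage.

Each generator is a pure function of its configuration (including a
mandatory seed), so all downstream analyses are testable without any
external dataset:

* :func:`gen_isotherm` -- noisy Hill / single-site anisotropy titrations
  over a stated concentration grid (default emulates a 0-800 nM protein
  titration against a 2.5 nM labeled probe);
* :func:`simulate_intensity_traces` -- Brownian-dynamics two-channel
  photon traces of a dual-color DNA mixture with incomplete labeling and
  a tunable bridged fraction, detected through a 3-D Gaussian confocal
  volume with Poisson photon noise;
* :func:`correlate_traces` -- a multi-tau correlator turning traces into
  correlation curves;
* :func:`gen_contact_map` -- a distance-decaying Poisson contact map with
  contact enrichment between co-bound anchor/target bin pairs at
  15-60 kb separations, plus the corresponding peak sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingIsotherm, anisotropy_model
from .correlation import CorrelationCurve
from .errors import ConfigError, InputError
from .hic import ContactTable, PeakSet

__all__ = [
    "FccsSimConfig",
    "HicSimConfig",
    "TwoChannelTrace",
    "gen_isotherm",
    "gen_competition",
    "simulate_intensity_traces",
    "correlate_traces",
    "gen_contact_map",
]

# Default titration grid: 12 concentrations spanning 0-800 nM, denser at
# the low end where the isotherms bend.
DEFAULT_CONC_GRID = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 450.0, 600.0, 800.0)


def gen_isotherm(kd: float, n: float, r_free: float, delta_r: float,
                 conc_grid=DEFAULT_CONC_GRID, sigma: float = 1.5,
                 seed: int = 0, probe_conc: float = 2.5,
                 label: str = "synthetic") -> BindingIsotherm:
    """Hill-model anisotropy titration with i.i.d. Gaussian noise.

    ``sigma`` is the per-point noise standard deviation in anisotropy
    units (default 1.5, a realistic plate-reader repeatability relative
    to binding amplitudes of ~10-30 units); ``sigma=0`` returns exact
    model values.  Reproducible for a given seed.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0:
        raise InputError("conc_grid must not be empty")
    rng = np.random.default_rng(seed)
    r = anisotropy_model(conc, r_free, delta_r, kd, n)
    if sigma > 0:
        r = r + rng.normal(0.0, sigma, conc.size)
    sig = np.full(conc.size, sigma) if sigma > 0 else None
    return BindingIsotherm(protein_conc=conc, anisotropy=r, sigma=sig,
                           probe_conc=probe_conc, label=label)


def gen_competition(ec50: float, r0: float, r_inf: float, conc_grid,
                    sigma: float = 1.5, seed: int = 0) -> tuple:
    """Hyperbolic-decay competition data; returns (conc, anisotropy)."""
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0:
        raise InputError("conc_grid must not be empty")
    rng = np.random.default_rng(seed)
    r = r_inf + (r0 - r_inf) / (1.0 + conc / ec50)
    if sigma > 0:
        r = r + rng.normal(0.0, sigma, conc.size)
    return conc, r


@dataclass
class FccsSimConfig:
    """Brownian-dynamics configuration for the two-color bridging assay.

    The emulated measurement: a 50/50 mixture of green- and red-labeled
    copies of the same DNA fragment diffusing through a 3-D Gaussian
    detection volume.  A fraction ``bridged_fraction`` of the DNA
    molecules is joined into rigid pairs (one diffusing entity carrying
    both molecules' dyes), emulating protein-mediated long-range DNA
    bridging.  Each molecule from the green (red) preparation actually
    carries its dye with probability ``label_eff_green``
    (``label_eff_red``); dark molecules still occupy pairs.

    Units: um, seconds, counts/s.  Defaults give a diffusion time
    ``tau_d = waist_xy**2 / (4 D) ~ 0.53 ms``, matching the scale of
    free-DNA diffusion times through a confocal spot.
    """

    seed: int
    n_molecules: int = 100
    diffusion_coeff: float = 29.48  # um^2/s -> tau_d ~ 0.53 ms with w = 0.25 um
    box_size: float = 4.0  # um, periodic cube
    waist_xy: float = 0.25  # um, lateral 1/e^2 waist
    structure_s: float = 5.0  # axial/lateral waist ratio
    brightness: float = 1.0e5  # detected counts/s per fluorophore at focus
    dt: float = 2.0e-5  # s per frame
    duration: float = 10.0  # s
    bridged_fraction: float = 0.0
    label_eff_green: float = 0.57
    label_eff_red: float = 0.97
    mix_fraction_green: float = 0.5
    crosstalk: float = 0.0  # green-dye leakage into the red channel (0 after PIE)
    initial_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        for name in ("n_molecules", "box_size", "waist_xy", "brightness", "dt", "duration"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.diffusion_coeff < 0:
            raise ConfigError("diffusion_coeff must be non-negative")
        if not self.structure_s > 1:
            raise ConfigError("structure_s must exceed 1")
        for name in ("bridged_fraction", "label_eff_green", "label_eff_red",
                     "mix_fraction_green", "crosstalk"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")

    @property
    def tau_d(self) -> float:
        """Expected diffusion time ``w^2 / 4D`` in seconds."""
        return self.waist_xy**2 / (4.0 * self.diffusion_coeff)


@dataclass
class TwoChannelTrace:
    """Two simultaneous photon-count traces sharing a frame time."""

    green: np.ndarray
    red: np.ndarray
    dt: float

    @property
    def duration(self) -> float:
        return self.green.size * self.dt


def simulate_intensity_traces(cfg: FccsSimConfig) -> TwoChannelTrace:
    """Simulate the two-channel photon traces of the bridging assay.

    Molecules (or bridged pairs, which diffuse as one entity) take
    Brownian steps of standard deviation ``sqrt(2 D dt)`` per axis in a
    periodic box; per-frame channel intensities sum each lit dye's
    brightness weighted by a 3-D Gaussian detection profile with waists
    ``(w, w, s*w)``, and photon counts are Poisson draws.  Entities that
    carry no lit dye are dropped (they cannot contribute signal).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    n_pairs = int(round(cfg.bridged_fraction * n / 2.0))
    n_single = n - 2 * n_pairs

    is_green = rng.random(n) < cfg.mix_fraction_green
    eff = np.where(is_green, cfg.label_eff_green, cfg.label_eff_red)
    lit = rng.random(n) < eff

    # Entities: first n_pairs pairs take molecules (2k, 2k+1), rest singles.
    n_entities = n_pairs + n_single
    b_g = np.zeros(n_entities)
    b_r = np.zeros(n_entities)

    def dye_contrib(mol_idx):
        g = cfg.brightness if (lit[mol_idx] and is_green[mol_idx]) else 0.0
        r = cfg.brightness if (lit[mol_idx] and not is_green[mol_idx]) else 0.0
        r += cfg.crosstalk * g
        return g, r

    for k in range(n_pairs):
        for m in (2 * k, 2 * k + 1):
            g, r = dye_contrib(m)
            b_g[k] += g
            b_r[k] += r
    for j in range(n_single):
        g, r = dye_contrib(2 * n_pairs + j)
        b_g[n_pairs + j] += g
        b_r[n_pairs + j] += r

    bright = (b_g + b_r) > 0
    b_g = b_g[bright]
    b_r = b_r[bright]
    n_frames = int(round(cfg.duration / cfg.dt))
    out_g = np.zeros(n_frames, dtype=np.int64)
    out_r = np.zeros(n_frames, dtype=np.int64)
    E = b_g.size
    if E == 0 or n_frames == 0:
        return TwoChannelTrace(green=out_g, red=out_r, dt=cfg.dt)

    L = cfg.box_size
    w = cfg.waist_xy
    wz = cfg.structure_s * w
    step_sigma = np.sqrt(2.0 * cfg.diffusion_coeff * cfg.dt)
    if step_sigma > w / 5.0:
        warnings.warn(
            "dt is large for this diffusion coefficient: per-axis step exceeds w/5; "
            "the correlation curve will be under-resolved at short lags",
            stacklevel=2,
        )

    if cfg.initial_positions is not None:
        pos = np.asarray(cfg.initial_positions, dtype=float)
        if pos.shape != (E, 3):
            raise ConfigError(
                f"initial_positions must have shape ({E}, 3) for the {E} lit entities"
            )
        pos = pos.copy()
    else:
        pos = rng.uniform(-L / 2.0, L / 2.0, (E, 3))

    chunk = max(1, int(4_000_000 // E))
    inv_w2 = 2.0 / w**2
    inv_wz2 = 2.0 / wz**2
    for start in range(0, n_frames, chunk):
        m = min(chunk, n_frames - start)
        if step_sigma > 0:
            path = rng.normal(0.0, step_sigma, (m, E, 3))
            np.cumsum(path, axis=0, out=path)
            path += pos
        else:
            path = np.broadcast_to(pos, (m, E, 3)).copy()
        # periodic wrap into [-L/2, L/2)
        np.mod(path + L / 2.0, L, out=path)
        path -= L / 2.0
        pos = path[-1].copy()
        mdf = np.exp(
            -inv_w2 * (path[:, :, 0] ** 2 + path[:, :, 1] ** 2)
            - inv_wz2 * path[:, :, 2] ** 2
        )
        out_g[start:start + m] = rng.poisson(mdf @ b_g * cfg.dt)
        out_r[start:start + m] = rng.poisson(mdf @ b_r * cfg.dt)
    return TwoChannelTrace(green=out_g, red=out_r, dt=cfg.dt)


def correlate_traces(trace_a, trace_b, dt: float | None = None, m: int = 16,
                     channel_pair: str = "cross") -> CorrelationCurve:
    """Multi-tau correlation of two equal-length intensity traces.

    Computes ``G(tau) = <dA(t) dB(t+tau)> / (<A><B>)`` on the standard
    multi-tau lag ladder: ``m`` linear lags at the native frame time,
    then ``m/2`` lags per cascade level with the traces rebinned by 2 at
    every level.  Pass the same array twice for an autocorrelation.
    ``trace_a``/``trace_b`` may be :class:`TwoChannelTrace` channels
    (plain arrays) with ``dt`` given explicitly.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("traces must be 1-D arrays of equal length")
    if dt is None or not dt > 0:
        raise InputError("a positive frame time dt is required")
    if m < 4 or m % 2:
        raise ConfigError("m must be an even integer >= 4")
    if a.size < 4 * m:
        raise InputError(f"traces must have at least {4 * m} samples")
    if a.mean() == 0 or b.mean() == 0:
        raise InputError("zero-mean trace cannot be normalized")

    lags = []
    gs = []
    aa, bb = a, b
    binw = 1
    level = 0
    while True:
        ks = range(0, m) if level == 0 else range(m // 2, m)
        for k in ks:
            if k >= aa.size // 2:
                break
            a0 = aa[: aa.size - k] if k else aa
            bk = bb[k:]
            denom = a0.mean() * bk.mean()
            if denom == 0:
                raise InputError("zero-mean trace segment cannot be normalized")
            lags.append(k * binw * dt)
            gs.append(float((a0 * bk).mean() / denom - 1.0))
        half = (aa.size // 2) * 2
        if half // 2 < 4 * m:
            break
        aa = aa[:half].reshape(-1, 2).mean(axis=1)
        bb = bb[:half].reshape(-1, 2).mean(axis=1)
        binw *= 2
        level += 1
    return CorrelationCurve(lag=np.asarray(lags), g=np.asarray(gs),
                            channel_pair=channel_pair)


@dataclass
class HicSimConfig:
    """Configuration of the synthetic contact map and peak sets.

    Contacts between bins at genomic distance ``d`` are Poisson with rate
    ``background * (d / bin_size)**(-alpha)`` (a power-law distance
    decay), multiplied by ``enrichment`` when one bin carries an anchor
    peak (BEAF32) and the other a co-bound target (CP190 AND Chromator by
    default) at separations within ``[enrich_d_min, enrich_d_max]``.
    Peaks are placed uniformly; a fraction ``p_chromator_at_cp190`` of
    Chromator peaks is co-located with CP190 peaks to create co-bound
    target bins.
    """

    seed: int
    chrom_sizes: dict = field(default_factory=lambda: {"chr2L": 2_000_000})
    bin_size: int = 500
    alpha: float = 1.0
    background: float = 10.0
    enrichment: float = 3.0
    enrich_d_min: int = 15000
    enrich_d_max: int = 60000
    max_dist: int = 70000
    n_beaf32: int = 200
    n_cp190: int = 300
    n_chromator: int = 300
    p_chromator_at_cp190: float = 0.6
    peak_halfwidth: int = 100
    target_mode: str = "all"  # enrichment requires all (or any) target factors

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        if not self.alpha > 0:
            raise ConfigError("decay exponent alpha must be positive")
        if self.enrichment < 1:
            raise ConfigError("enrichment must be >= 1")
        if self.target_mode not in ("all", "any"):
            raise ConfigError("target_mode must be 'all' or 'any'")
        for chrom, size in self.chrom_sizes.items():
            if size < 4 * self.bin_size:
                raise ConfigError(f"chromosome {chrom} too short for bin_size")
        if self.max_dist < self.enrich_d_max:
            raise ConfigError("max_dist must cover the enrichment distance range")


def _place_peaks(rng, chrom_sizes, n, halfwidth, at_positions=None, p_at=0.0):
    """Uniform peak placement; optionally co-locate a fraction at given sites."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    intervals = []
    counts = rng.multinomial(n, probs)
    for c_idx, (chrom, k) in enumerate(zip(chroms, counts)):
        size = int(sizes[c_idx])
        mids = rng.integers(halfwidth, size - halfwidth, k)
        if at_positions is not None and p_at > 0:
            host = [m for cc, m in at_positions if cc == chrom]
            if host:
                take = rng.random(k) < p_at
                mids = mids.copy()
                mids[take] = rng.choice(host, take.sum())
        for m in mids:
            intervals.append((chrom, int(m) - halfwidth, int(m) + halfwidth))
    return intervals


def gen_contact_map(cfg: HicSimConfig):
    """Generate ``(ContactTable, {name: PeakSet})`` per the configuration.

    Returns the sparse contact table (zero-count bin pairs omitted) and
    the BEAF32 / CP190 / Chromator peak sets.  Byte-identical for a given
    configuration and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    bs = cfg.bin_size

    beaf = PeakSet("BEAF32", _place_peaks(rng, cfg.chrom_sizes, cfg.n_beaf32, cfg.peak_halfwidth))
    cp190 = PeakSet("CP190", _place_peaks(rng, cfg.chrom_sizes, cfg.n_cp190, cfg.peak_halfwidth))
    chromator = PeakSet(
        "Chromator",
        _place_peaks(rng, cfg.chrom_sizes, cfg.n_chromator, cfg.peak_halfwidth,
                     at_positions=cp190.midpoints(), p_at=cfg.p_chromator_at_cp190),
    )

    records = {"chrom": [], "bin_i": [], "bin_j": [], "count": []}
    for chrom, size in cfg.chrom_sizes.items():
        nb = size // bs
        beaf_flag = np.zeros(nb, dtype=bool)
        cp_flag = np.zeros(nb, dtype=bool)
        chro_flag = np.zeros(nb, dtype=bool)
        for flag, ps in ((beaf_flag, beaf), (cp_flag, cp190), (chro_flag, chromator)):
            for c, mid in ps.midpoints():
                if c == chrom and mid // bs < nb:
                    flag[mid // bs] = True
        if cfg.target_mode == "all":
            tgt_flag = cp_flag & chro_flag
        else:
            tgt_flag = cp_flag | chro_flag

        kmax = min(cfg.max_dist // bs, nb - 1)
        for k in range(1, kmax + 1):
            d = k * bs
            rate = cfg.background * float(k) ** (-cfg.alpha)
            rates = np.full(nb - k, rate)
            if cfg.enrichment > 1 and cfg.enrich_d_min <= d <= cfg.enrich_d_max:
                i = np.arange(nb - k)
                enr = (beaf_flag[i] & tgt_flag[i + k]) | (beaf_flag[i + k] & tgt_flag[i])
                rates[enr] *= cfg.enrichment
            counts = rng.poisson(rates)
            nz = np.nonzero(counts)[0]
            if nz.size:
                records["chrom"].extend([chrom] * nz.size)
                records["bin_i"].extend((nz * bs).tolist())
                records["bin_j"].extend(((nz + k) * bs).tolist())
                records["count"].extend(counts[nz].tolist())

    df = pd.DataFrame(records, columns=["chrom", "bin_i", "bin_j", "count"])
    table = ContactTable(bin_size=bs, df=df, genome=dict(cfg.chrom_sizes))
    return table, {"BEAF32": beaf, "CP190": cp190, "Chromator": chromator}
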