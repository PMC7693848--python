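"""Synthetic-data generators for every pipeline input.

The generators emulate the study conditions the analysis assumes: a
two-Gaussian cross-channel intensity profile (equilibrium peaks near
100 µm and 160 µm), 15-level spiking series between 50 and 3500 cells
with per-cell binomial capture, two-cycle WBC carryover, and Trypan-blue
viability counts.  Count noise is binomial throughout — the simplest model
consistent with independent per-cell capture — and every generator is
bit-reproducible for a fixed seed.

Default rates: cycle-1 CTC capture 0.771 with conditional cycle-2 capture
0.849 (so the two-cycle cumulative capture is 0.655); WBC carryover 0.369
then 0.317 (so two-cycle depletion averages 88.3%); inlet viability 0.816.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .distributions import FWHM_PER_SIGMA, IntensityProfile
from .enrichment import CycleCounts, SpikingSeries, ViabilityCounts
from .exceptions import SpiralfoilError

__all__ = [
    "SynthConfig",
    "default_spiking_levels",
    "gen_intensity_profile",
    "gen_spiking_series",
    "gen_cycle_counts",
    "gen_viability_counts",
    "write_fixtures",
]


def default_spiking_levels(n_levels: int = 15, lo: int = 50, hi: int = 3500) -> tuple[int, ...]:
    """Geometric ladder of spiking levels, the serial-dilution design."""
    return tuple(
        int(round(v)) for v in np.geomspace(lo, hi, n_levels)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of all generators; defaults are the study conditions."""

    seed: int = 0
    peaks: tuple[float, float] = (100.0, 160.0)       # µm, CTC then WBC
    fwhms: tuple[float, float] = (15.8, 15.8)         # µm
    amplitudes: tuple[float, float] = (1.0, 0.9)
    baseline: float = 0.05
    noise_sd: float = 0.02                            # intensity units
    channel_width: float = 300.0                      # µm
    capture_probs: tuple[float, float] = (0.771, 0.849)  # c1, conditional c2
    wbc_carryover: tuple[float, float] = (0.369, 0.317)  # c1, conditional c2
    spiking_levels: tuple[int, ...] = field(default_factory=default_spiking_levels)
    inlet_viability: float = 0.816

    def __post_init__(self) -> None:
        probs = (
            *self.capture_probs, *self.wbc_carryover, self.inlet_viability
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SpiralfoilError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SpiralfoilError("noise level cannot be negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def gen_intensity_profile(cfg: SynthConfig, n_samples: int = 256) -> IntensityProfile:
    """Two Gaussians plus baseline plus additive Gaussian noise."""
    if n_samples < 32:
        raise SpiralfoilError("need at least 32 samples")
    x = np.linspace(0.0, cfg.channel_width, n_samples)
    sigmas = tuple(w / FWHM_PER_SIGMA for w in cfg.fwhms)
    y = np.full_like(x, cfg.baseline)
    for amp, mu, sig in zip(cfg.amplitudes, cfg.peaks, sigmas):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    if cfg.noise_sd > 0:
        y = y + cfg.rng(stream=1).normal(0.0, cfg.noise_sd, size=x.size)
    return IntensityProfile(x, y)


def gen_spiking_series(cfg: SynthConfig, cycle: int = 1) -> SpikingSeries:
    """Binomial capture at each spiking level.

    Cycle 1 draws recovered ~ Binomial(n, p1); cycle 2 re-captures the
    cycle-1 survivors with the conditional probability, so the cumulative
    rate is p1·p2.
    """
    if cycle not in (1, 2):
        raise SpiralfoilError("cycle must be 1 or 2")
    rng = cfg.rng(stream=10 + cycle)
    levels = np.asarray(cfg.spiking_levels, dtype=int)
    p1, p2 = cfg.capture_probs
    rec1 = rng.binomial(levels, p1)
    recovered = rec1 if cycle == 1 else rng.binomial(rec1, p2)
    return SpikingSeries(levels=levels, recovered=recovered)


def gen_cycle_counts(
    cfg: SynthConfig, wbc_inlet: int = 10_000_000, mcf7_inlet: int = 1000
) -> CycleCounts:
    """Two-cycle WBC carryover and MCF7 capture counts.

    WBCs carried to the CTC outlet are binomially thinned each cycle;
    MCF7 escape to waste is the binomial complement of capture.
    """
    import warnings

    if wbc_inlet < 10_000 * max(mcf7_inlet, 1):
        warnings.warn(
            "WBC inlet is not ≫ MCF7 inlet; counting model assumes rarity",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = cfg.rng(stream=20)
    c1, c2 = cfg.wbc_carryover
    wbc_c1 = rng.binomial(wbc_inlet, c1)
    wbc_c2 = rng.binomial(wbc_c1, c2)
    p1, p2 = cfg.capture_probs
    kept1 = rng.binomial(mcf7_inlet, p1)
    kept2 = rng.binomial(kept1, p2)
    return CycleCounts(
        wbc_inlet=wbc_inlet,
        wbc_ctc_c1=int(wbc_c1),
        wbc_ctc_c2=int(wbc_c2),
        mcf7_inlet=mcf7_inlet,
        mcf7_waste_c1=int(mcf7_inlet - kept1),
        mcf7_waste_c2=int(kept1 - kept2),
    )


def gen_viability_counts(
    cfg: SynthConfig,
    n_cells: int = 100_000,
    loss_prob: float = 0.157,
) -> ViabilityCounts:
    """Trypan-blue counts with binomial inlet viability and loss thinning.

    The loss probability applies independently to viable and non-viable
    pools, matching the observation that total and viable losses track
    each other.
    """
    if not (0.0 <= loss_prob <= 1.0):
        raise SpiralfoilError("loss probability must lie in [0, 1]")
    rng = cfg.rng(stream=30)
    viable_in = int(rng.binomial(n_cells, cfg.inlet_viability))
    dead_in = n_cells - viable_in
    viable_out = int(rng.binomial(viable_in, 1.0 - loss_prob))
    dead_out = int(rng.binomial(dead_in, 1.0 - loss_prob))
    return ViabilityCounts(
        viable_inlet=viable_in,
        total_inlet=n_cells,
        viable_outlets=viable_out,
        total_outlets=viable_out + dead_out,
    )


def write_fixtures(cfg: SynthConfig, outdir: str | Path) -> dict[str, str]:
    """Emit every generator's output as CSV plus a manifest JSON.

    The manifest records the seed and all parameters so a run can be
    reproduced bit-for-bit.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    profile = gen_intensity_profile(cfg)
    ppath = outdir / "intensity_profile.csv"
    profile.to_csv(ppath)
    files["intensity_profile"] = ppath.name

    frames = []
    for cycle in (1, 2):
        s = gen_spiking_series(cfg, cycle=cycle)
        frames.append(
            pd.DataFrame(
                {"cycle": cycle, "n_spiked": s.levels.astype(int),
                 "n_recovered": s.recovered.astype(int)}
            )
        )
    spath = outdir / "spiking_series.csv"
    pd.concat(frames, ignore_index=True).to_csv(spath, index=False)
    files["spiking_series"] = spath.name

    cc = gen_cycle_counts(cfg)
    vc = gen_viability_counts(cfg)
    rows = [
        dict(sample_id="synthetic", cycle=0, location="inlet",
             wbc_count=cc.wbc_inlet, mcf7_count=cc.mcf7_inlet,
             viable_count=vc.viable_inlet, total_count=vc.total_inlet),
        dict(sample_id="synthetic", cycle=1, location="ctc",
             wbc_count=cc.wbc_ctc_c1, mcf7_count="",
             viable_count="", total_count=""),
        dict(sample_id="synthetic", cycle=1, location="waste",
             wbc_count="", mcf7_count=cc.mcf7_waste_c1,
             viable_count="", total_count=""),
        dict(sample_id="synthetic", cycle=2, location="ctc",
             wbc_count=cc.wbc_ctc_c2, mcf7_count="",
             viable_count=vc.viable_outlets, total_count=vc.total_outlets),
        dict(sample_id="synthetic", cycle=2, location="waste",
             wbc_count="", mcf7_count=cc.mcf7_waste_c2,
             viable_count="", total_count=""),
    ]
    cpath = outdir / "cycle_counts.csv"
    pd.DataFrame(rows).to_csv(cpath, index=False)
    files["cycle_counts"] = cpath.name

    manifest = {"generator": "spiralfoil.synth", "config": asdict(cfg), "files": files}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = mpath.name
    return files
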