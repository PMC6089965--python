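"""Seeded generators for every fixture the analysis pipeline consumes.

Transfer curves with multiplicative noise, dose-response datasets with the
assay's negative-control noise structure, and labeled chain trajectories
with controllable orientational order and hydrogen-bond occupancy.  One
master seed drives everything; each generator derives an independent
substream via a fixed offset, so adding draws in one generator never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import counting, dose_model, egofet
from .assay_metrics import NOISE_PRESETS, NoiseStats
from .traj_analysis import ChainTrajectory

__all__ = [
    "GeneratorConfig",
    "substream",
    "gen_transfer_curves",
    "gen_dose_dataset",
    "gen_chain_trajectory",
    "sample_axial_cos",
]

# fixed substream offsets per generator family
_STREAM_TRANSFER = 1
_STREAM_DOSE = 2
_STREAM_TRAJECTORY = 3


def substream(seed: int, stream: int) -> np.random.Generator:
    """Independent random stream derived from (seed, stream offset)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator settings; the seed is echoed in every artifact.

    ``dilution`` holds (c0_zM, factor, n_steps, per_step_cv, volume_ul);
    ``trajectory`` holds (n_chains, n_frames, order concentration a,
    target occupancy fraction).
    """

    seed: int = 0
    transfer_noise_sd: float = 0.01
    control_noise: NoiseStats = NOISE_PRESETS["pbs"]
    device: egofet.DeviceParams = field(default_factory=egofet.DeviceParams)
    domain_model: dose_model.DomainModel = None
    dilution: tuple = (6.67e8, 10.0, 11, 0.015, 100.0)
    trajectory: tuple = (64, 200, 4.0, 0.7)

    def __post_init__(self) -> None:
        if self.transfer_noise_sd < 0:
            raise ValueError("transfer_noise_sd must be >= 0")
        if self.domain_model is None:
            object.__setattr__(
                self, "domain_model", dose_model.equal_domain_model(6, r_max=0.65)
            )


def gen_transfer_curves(
    config: GeneratorConfig, vt_sequence
) -> list[egofet.TransferCurve]:
    """Square-law transfer curves at each threshold in ``vt_sequence``.

    Each curve is the noiseless square law at that V_T multiplied by
    i.i.d. lognormal noise exp(N(0, σ)) per sample (median-unbiased
    multiplicative noise, σ = ``transfer_noise_sd``).  Deterministic for a
    fixed config seed.
    """
    vt_sequence = list(vt_sequence)
    if not vt_sequence:
        raise ValueError("vt_sequence must not be empty")
    rng = substream(config.seed, _STREAM_TRANSFER)
    out = []
    for vt in vt_sequence:
        params = egofet.DeviceParams(
            width=config.device.width,
            length=config.device.length,
            mobility_capacitance=config.device.mobility_capacitance,
            vt=vt,
        )
        clean = egofet.transfer_curve(params)
        noise = (
            np.exp(rng.normal(0.0, config.transfer_noise_sd, size=clean.id.shape))
            if config.transfer_noise_sd > 0
            else 1.0
        )
        out.append(egofet.TransferCurve(vg=clean.vg, id=clean.id * noise, vd=clean.vd))
    return out


def gen_dose_dataset(
    config: GeneratorConfig, n_replicates: int = 3
) -> tuple[dose_model.DoseResponseCurve, dose_model.DomainModel]:
    """Synthetic dose-response dataset plus its ground-truth model.

    One simulated gate is incubated most-dilute-first through the whole
    dilution series; domain flipping is irreversible, so the flipped set
    only grows across incubations (incremental Poisson bindings per step).
    The reported response per dose averages ``n_replicates`` independent
    gates and adds the negative-control noise (mean + Gaussian SD of the
    chosen preset) to every replicate.  Response SDs are the replicate SDs
    (sample SD over the gates), floored at the control noise SD.
    """
    c0, factor, n_steps, cv, volume = config.dilution
    series = counting.build_dilution_series(c0, factor, int(n_steps), cv, volume)
    ordered = series.measurement_order()
    lam_steps = np.array([s.lam for s in ordered])
    cum_lam = np.cumsum(lam_steps)

    model = config.domain_model
    rng = substream(config.seed, _STREAM_DOSE)
    a = model.fractions
    eta = model.capture_efficiency
    resp = np.zeros((n_replicates, len(ordered)))
    for rep in range(n_replicates):
        flipped = np.zeros(len(a), dtype=bool)
        for i, lam_i in enumerate(lam_steps):
            m = rng.poisson(eta * lam_i)
            if m > 0:
                hits = rng.multinomial(m, a)
                flipped |= hits > 0
            clean = model.r_max * a[flipped].sum()
            noise = rng.normal(config.control_noise.mean, config.control_noise.sd)
            resp[rep, i] = clean + noise
    sigmas = resp.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(len(ordered))
    sigmas = np.maximum(sigmas, config.control_noise.sd)
    data = dose_model.DoseResponseCurve(
        doses=cum_lam,
        responses=resp.mean(axis=0),
        sigmas=sigmas,
        noise_mean=config.control_noise.mean,
        noise_sd=config.control_noise.sd,
    )
    return data, model


def sample_axial_cos(a: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample cosθ from the axial distribution p(c) ∝ exp(a·c²) on [−1, 1].

    ``a`` is the order concentration parameter: a = 0 is isotropic, large a
    concentrates the orientations along the axis.  Rejection sampling with
    a uniform proposal (acceptance exp(a(c² − 1)) ≤ 1 for a ≥ 0).
    """
    if a < 0:
        raise ValueError("concentration parameter must be >= 0")
    a = min(a, 700.0)  # clamp: beyond this the distribution is numerically degenerate
    out = np.empty(size)
    n = 0
    while n < size:
        want = size - n
        # oversample roughly by the inverse acceptance (~sqrt(a)) with a cap
        batch = min(max(64, int(want * (2.0 + 2.0 * math.sqrt(a)))), 2_000_000)
        c = rng.uniform(-1.0, 1.0, batch)
        keep = c[rng.uniform(0.0, 1.0, batch) < np.exp(a * (c**2 - 1.0))]
        take = min(len(keep), want)
        out[n : n + take] = keep[:take]
        n += take
    return out


def gen_chain_trajectory(config: GeneratorConfig) -> ChainTrajectory:
    """Labeled chain trajectory with tunable order and H-bond occupancy.

    Chains sit on a square grid (5 Å pitch) with sulfur anchors at z = 0;
    each frame draws every chain's orientation independently from the
    axial distribution exp(a·cos²θ) (upper hemisphere) and places the
    hydroxyl oxygen one chain length (4 Å) along it.  Donor–acceptor
    triplets between neighbouring chains are placed in ideal hydrogen-bond
    geometry (2.9 Å, 180°) in a Bernoulli(occupancy) fraction of frames
    and broken geometry (3.8 Å) otherwise.
    """
    n_chains, n_frames, a, occupancy = config.trajectory
    n_chains, n_frames = int(n_chains), int(n_frames)
    if n_chains < 2 or n_frames < 2:
        raise ValueError("need at least 2 chains and 2 frames")
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    rng = substream(config.seed, _STREAM_TRAJECTORY)

    pitch, chain_len = 5.0, 4.0
    side = math.ceil(math.sqrt(n_chains))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    anchors = np.column_stack(
        [gx.ravel()[:n_chains] * pitch, gy.ravel()[:n_chains] * pitch,
         np.zeros(n_chains)]
    )
    sulfur = np.broadcast_to(anchors, (n_frames, n_chains, 3)).copy()

    c = np.abs(sample_axial_cos(a, n_frames * n_chains, rng)).reshape(n_frames, n_chains)
    phi = rng.uniform(0.0, 2.0 * math.pi, (n_frames, n_chains))
    s = np.sqrt(1.0 - c**2)
    u = np.stack([s * np.cos(phi), s * np.sin(phi), c], axis=-1)
    oxygen = sulfur + chain_len * u

    ids = tuple(f"c{i}" for i in range(n_chains))
    pairs = tuple((ids[i], ids[i + 1]) for i in range(n_chains - 1))
    n_pairs = len(pairs)
    bonded = rng.uniform(size=(n_frames, n_pairs)) < occupancy
    # triplets along +x from the donor chain's oxygen; 2.9 Å D-A when bonded
    base = oxygen[:, :-1, :]
    donor = base
    hydrogen = base + np.array([1.0, 0.0, 0.0])
    da = np.where(bonded[..., None], 2.9, 3.8)
    acceptor = base + da * np.array([1.0, 0.0, 0.0])
    return ChainTrajectory(
        sulfur=sulfur,
        oxygen=oxygen,
        chain_ids=ids,
        hbond_donor=donor,
        hbond_hydrogen=hydrogen,
        hbond_acceptor=acceptor,
        hbond_pairs=pairs,
    )
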