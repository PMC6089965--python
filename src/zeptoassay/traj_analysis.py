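"""Orientational order and hydrogen bonding of monolayer chain trajectories.

Consumes labeled coordinate trajectories of self-assembled-monolayer
chains (sulfur anchor and hydroxyl-oxygen endpoint per chain, plus labeled
donor–hydrogen–acceptor triplets) and computes:

- hydrogen-bond presence and per-pair occupancy with a geometric
  criterion (donor–acceptor distance ≤ 3 Å and donor–H–acceptor angle
  ≥ 150°, vertex at the hydrogen);
- the chain tilt angle θ between the S→O chain vector and the surface
  normal (z, the gating-field direction);
- the nematic order parameter P₂, either against the fixed z-axis or
  against the self-consistent director (largest eigenvalue of the averaged
  Q-tensor);
- a dynamic order parameter S: the second Legendre polynomial of each
  chain's *time-averaged* cos²θ, averaged over chains — it separates
  chains that are stably tilted (S reflects the frozen tilt) from chains
  that wobble isotropically frame-to-frame (S → 0).

Trajectories are assumed unwrapped (no periodic imaging); a validation
pass rejects triplets whose atoms are implausibly far apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HBondCriterion",
    "ChainTrajectory",
    "OrderParams",
    "hbond_present",
    "hbond_occupancy",
    "occupancy_table",
    "chain_tilt_theta",
    "nematic_p2",
    "dynamic_s",
    "order_params",
]

#: Sanity limits on triplet geometry: a covalently bound hydrogen sits
#: within 1.5 Å of its donor; distances beyond 100 Å inside one triplet
#: indicate a wrapped/broken trajectory.
MAX_DH_COVALENT = 1.5
MAX_TRIPLET_SPAN = 100.0


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (inclusive thresholds)."""

    max_da_distance: float = 3.0  # Å, donor–acceptor
    min_dha_angle: float = 150.0  # degrees, donor–H–acceptor, vertex at H

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be > 0")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class ChainTrajectory:
    """Labeled chain trajectory.

    Attributes
    ----------
    sulfur, oxygen : np.ndarray
        (n_frames, n_chains, 3) positions in Å of the sulfur anchor and the
        hydroxyl oxygen of every chain.
    chain_ids : tuple of str
        Chain identifiers, one per chain column.
    hbond_donor, hbond_hydrogen, hbond_acceptor : np.ndarray
        (n_frames, n_pairs, 3) positions of the labeled donor atom,
        hydrogen and acceptor atom of each tracked donor–acceptor pair.
    hbond_pairs : tuple of (str, str)
        (donor_id, acceptor_id) labels, one per pair column.
    """

    sulfur: np.ndarray
    oxygen: np.ndarray
    chain_ids: tuple
    hbond_donor: np.ndarray = None
    hbond_hydrogen: np.ndarray = None
    hbond_acceptor: np.ndarray = None
    hbond_pairs: tuple = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.sulfur, dtype=float)
        o = np.asarray(self.oxygen, dtype=float)
        if s.ndim != 3 or s.shape[-1] != 3 or s.shape != o.shape:
            raise ValueError("sulfur/oxygen must be (n_frames, n_chains, 3) arrays")
        if s.shape[0] < 1:
            raise ValueError("need at least one frame")
        if len(self.chain_ids) != s.shape[1]:
            raise ValueError("chain_ids length must match the chain axis")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(o))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "sulfur", s)
        object.__setattr__(self, "oxygen", o)
        object.__setattr__(self, "chain_ids", tuple(self.chain_ids))

        if self.hbond_donor is not None:
            d = np.asarray(self.hbond_donor, dtype=float)
            h = np.asarray(self.hbond_hydrogen, dtype=float)
            a = np.asarray(self.hbond_acceptor, dtype=float)
            if not (d.shape == h.shape == a.shape) or d.ndim != 3:
                raise ValueError("hbond arrays must share shape (n_frames, n_pairs, 3)")
            if d.shape[0] != s.shape[0]:
                raise ValueError("hbond arrays must cover every frame")
            if len(self.hbond_pairs) != d.shape[1]:
                raise ValueError("hbond_pairs length must match the pair axis")
            if not all(np.all(np.isfinite(x)) for x in (d, h, a)):
                raise ValueError("coordinates must be finite")
            dh = np.linalg.norm(h - d, axis=-1)
            if np.any(dh >= MAX_DH_COVALENT):
                raise ValueError(
                    f"donor-hydrogen distance >= {MAX_DH_COVALENT} Å: not a covalent D-H"
                )
            da = np.linalg.norm(a - d, axis=-1)
            if np.any(da > MAX_TRIPLET_SPAN):
                raise ValueError(
                    f"triplet span > {MAX_TRIPLET_SPAN} Å: trajectory looks wrapped"
                )
            object.__setattr__(self, "hbond_donor", d)
            object.__setattr__(self, "hbond_hydrogen", h)
            object.__setattr__(self, "hbond_acceptor", a)
            object.__setattr__(self, "hbond_pairs", tuple(map(tuple, self.hbond_pairs)))

    @property
    def n_frames(self) -> int:
        return self.sulfur.shape[0]

    @property
    def n_chains(self) -> int:
        return self.sulfur.shape[1]

    def orientations(self) -> np.ndarray:
        """Unit S→O chain vectors, shape (n_frames, n_chains, 3)."""
        v = self.oxygen - self.sulfur
        norms = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-length chain vector")
        return v / norms


def hbond_present(donor, hydrogen, acceptor, crit: HBondCriterion = HBondCriterion()):
    """Whether a donor–hydrogen–acceptor triplet forms a hydrogen bond.

    True iff the donor–acceptor distance is ≤ the cutoff and the
    donor–H–acceptor angle (vertex at the hydrogen) is ≥ the cutoff, both
    inclusive.  Accepts single points (shape (3,)) or stacked arrays
    (..., 3); invariant under rigid motions by construction.
    """
    d = np.asarray(donor, dtype=float)
    h = np.asarray(hydrogen, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    hd = d - h
    ha = a - h
    nhd = np.linalg.norm(hd, axis=-1)
    nha = np.linalg.norm(ha, axis=-1)
    if np.any(nhd == 0) or np.any(nha == 0):
        raise ValueError("hydrogen coincides with donor or acceptor: angle undefined")
    cosang = np.clip(np.sum(hd * ha, axis=-1) / (nhd * nha), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    da = np.linalg.norm(a - d, axis=-1)
    ok = (da <= crit.max_da_distance) & (angle >= crit.min_dha_angle)
    return bool(ok) if ok.ndim == 0 else ok


def hbond_occupancy(
    traj: ChainTrajectory,
    pair: tuple,
    crit: HBondCriterion = HBondCriterion(),
) -> float:
    """Percentage of frames in which a donor–acceptor pair is hydrogen-bonded."""
    if traj.hbond_donor is None:
        raise ValueError("trajectory carries no hydrogen-bond triplets")
    pair = tuple(pair)
    try:
        j = traj.hbond_pairs.index(pair)
    except ValueError:
        raise KeyError(f"unknown donor-acceptor pair {pair!r}") from None
    present = hbond_present(
        traj.hbond_donor[:, j], traj.hbond_hydrogen[:, j], traj.hbond_acceptor[:, j], crit
    )
    return 100.0 * float(np.mean(present))


def occupancy_table(
    traj: ChainTrajectory, crit: HBondCriterion = HBondCriterion()
) -> pd.DataFrame:
    """Occupancy of every tracked pair: columns donor_id, acceptor_id, occupancy_pct."""
    rows = [
        {
            "donor_id": dnr,
            "acceptor_id": acc,
            "occupancy_pct": hbond_occupancy(traj, (dnr, acc), crit),
        }
        for dnr, acc in traj.hbond_pairs
    ]
    return pd.DataFrame(rows, columns=["donor_id", "acceptor_id", "occupancy_pct"])


def chain_tilt_theta(sulfur, oxygen) -> float:
    """Tilt angle θ (degrees) of the S→O chain vector against the z-axis.

    z is the surface normal and gating-field direction; θ ∈ [0, 180].
    """
    v = np.asarray(oxygen, dtype=float) - np.asarray(sulfur, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    if np.any(n == 0):
        raise ValueError("zero-length chain vector")
    cos = np.clip(v[..., 2] / n, -1.0, 1.0)
    out = np.degrees(np.arccos(cos))
    return float(out) if out.ndim == 0 else out


def nematic_p2(traj: ChainTrajectory, axis: str = "z") -> float:
    """Nematic order parameter P₂ of the chain vectors.

    ``axis="z"``: ⟨(3 cos²θ − 1)/2⟩ over all chains and frames against the
    fixed surface normal.  ``axis="director"``: largest eigenvalue of the
    averaged Q-tensor Q = ⟨(3 u⊗u − I)/2⟩, i.e. the order against the
    self-consistent director; always ≥ the fixed-axis value.  1 = aligned,
    0 = isotropic, −0.5 = perpendicular to the axis.
    """
    if traj.n_chains < 2:
        raise ValueError("need at least 2 chains")
    u = traj.orientations().reshape(-1, 3)
    if axis == "z":
        c2 = u[:, 2] ** 2
        return float(np.mean(1.5 * c2 - 0.5))
    if axis == "director":
        q = 1.5 * np.einsum("ni,nj->ij", u, u) / len(u) - 0.5 * np.eye(3)
        return float(np.linalg.eigvalsh(q)[-1])
    raise ValueError(f"axis must be 'z' or 'director', got {axis!r}")


def dynamic_s(traj: ChainTrajectory) -> float:
    """Dynamic order parameter S from per-chain time-averaged orientation.

    S = ⟨ (3⟨cos²θ_i⟩_t − 1)/2 ⟩ over chains, with the time average taken
    per chain against the fixed z-axis.  Chains stably tilted past the
    magic angle give S < 0; isotropic frame-to-frame wobbling drives the
    per-chain time averages to 1/3 and S to 0, so S grows as the
    orientational order becomes *stable* in time.
    """
    if traj.n_frames < 2:
        raise ValueError("dynamic order needs at least 2 frames")
    u = traj.orientations()
    c2_t = np.mean(u[..., 2] ** 2, axis=0)  # per-chain time average
    return float(np.mean(1.5 * c2_t - 0.5))


@dataclass(frozen=True)
class OrderParams:
    """Summary order parameters of a trajectory."""

    p2: float  # fixed-axis nematic order
    p2_director: float  # Q-tensor (director) nematic order
    s_dynamic: float
    mean_theta: float  # degrees

    def __post_init__(self) -> None:
        for v in (self.p2, self.p2_director, self.s_dynamic):
            if not -0.5 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError("order parameters must lie in [-0.5, 1]")


def order_params(traj: ChainTrajectory) -> OrderParams:
    """Compute P₂ (both variants), dynamic S and the mean tilt angle."""
    theta = chain_tilt_theta(traj.sulfur, traj.oxygen)
    return OrderParams(
        p2=nematic_p2(traj, "z"),
        p2_director=nematic_p2(traj, "director"),
        s_dynamic=dynamic_s(traj),
        mean_theta=float(np.mean(theta)),
    )
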