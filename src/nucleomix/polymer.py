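"""Brownian-dynamics simulator of confined bead-spring chromosome chains
with transient crosslinking of nucleolar beads.

The model coarse-grains chromatin into beads of ~5 kbp connected by
wormlike-chain (WLC) entropic springs, confined to a spherical nucleus with
chain ends tethered to the nuclear envelope.  Within the nucleolus
(a contiguous run of beads), SMC-protein-mediated crosslinks form
transiently between *active* beads closer than a capture radius
``d_link``.  Each nucleolar bead switches stochastically between an active
and an inactive state: active durations are drawn from N(mu, (mu/5)^2) and
inactive durations from N(mu/9, (mu/45)^2), so the single kinetic
timescale ``mu`` (seconds) controls crosslink kinetics.  A crosslink is an
extra WLC spring between its two beads; it breaks when either endpoint
turns inactive.  Each bead carries at most one crosslink at a time;
partners are drawn uniformly at random among the active, unlinked,
non-adjacent nucleolar pairs within capture range (a nearest-first greedy
policy is available as an option).

Dynamics are overdamped (Euler--Maruyama): ``x <- x + (F/drag) dt +
sqrt(2 D dt) xi`` with isotropic Stokes drag and thermal diffusivity
``D = kT/drag``.  Tethered beads are pinned; all other beads are projected
back inside the nucleus after each step.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ConfigurationError",
    "StabilityError",
    "GenomeTopology",
    "SimParams",
    "SimState",
    "Trajectory",
    "nucleolus_preset",
    "genome_preset",
    "scaled_nucleus_radius",
    "init_configuration",
    "compute_forces",
    "step_dynamics",
    "update_activity",
    "match_crosslinks",
    "simulate",
    "sample_state_durations",
]


class ConfigurationError(ValueError):
    """Raised when a chain cannot be laid out in the given nucleus."""


class StabilityError(RuntimeError):
    """Raised when the integrator's per-step displacement bound is violated."""


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class GenomeTopology:
    """Bead/chain layout of the simulated genome.

    ``chains`` holds one entry per chromosome arm: ``(first, last,
    tether_start, tether_end)`` where ``first``/``last`` are inclusive bead
    indices and the tether entries are unit 3-vectors giving the anchor
    direction on the nuclear envelope (``None`` = untethered end).
    ``nucleolar_mask`` flags the contiguous run of crosslink-competent
    (rDNA) beads.  ``bead_bp`` records the genomic coarse-graining.
    """

    n_beads: int
    chains: list
    nucleolar_mask: np.ndarray
    bead_bp: int = 5000
    # additional (bead index, unit direction) envelope anchors along a
    # chain's interior, emulating membrane association of the rDNA
    extra_tethers: list = field(default_factory=list)

    def __post_init__(self):
        self.nucleolar_mask = np.asarray(self.nucleolar_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.nucleolar_mask.shape != (self.n_beads,):
            raise ValueError("nucleolar_mask length must equal n_beads")
        covered = np.zeros(self.n_beads, dtype=bool)
        for first, last, *_ in self.chains:
            if not (0 <= first <= last < self.n_beads):
                raise ValueError(f"chain ({first}, {last}) out of range")
            if covered[first : last + 1].any():
                raise ValueError("chains overlap")
            covered[first : last + 1] = True
        if not covered.all():
            raise ValueError("chains do not partition bead indices")
        idx = np.flatnonzero(self.nucleolar_mask)
        if idx.size:
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("nucleolar beads must be contiguous")
            chain_of = self.chain_id
            if len(set(chain_of[idx])) != 1:
                raise ValueError("nucleolar beads must lie on a single chain")

    @property
    def chain_id(self) -> np.ndarray:
        cid = np.empty(self.n_beads, dtype=np.int64)
        for k, (first, last, *_) in enumerate(self.chains):
            cid[first : last + 1] = k
        return cid

    @property
    def bonds(self) -> np.ndarray:
        """Backbone springs: (n_bonds, 2) array of neighboring bead pairs."""
        out = []
        for first, last, *_ in self.chains:
            for i in range(first, last):
                out.append((i, i + 1))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    @property
    def tethered(self) -> np.ndarray:
        """Boolean mask of beads pinned to the nuclear envelope."""
        mask = np.zeros(self.n_beads, dtype=bool)
        for first, last, t0, t1 in self.chains:
            if t0 is not None:
                mask[first] = True
            if t1 is not None:
                mask[last] = True
        for idx, _ in self.extra_tethers:
            mask[idx] = True
        return mask

    def tether_positions(self, radius: float) -> dict:
        """Map bead index -> anchored 3D position on the sphere of ``radius``."""
        out = {}
        for first, last, t0, t1 in self.chains:
            if t0 is not None:
                out[first] = radius * np.asarray(t0, dtype=float)
            if t1 is not None:
                out[last] = radius * np.asarray(t1, dtype=float)
        for idx, vec in self.extra_tethers:
            out[idx] = radius * np.asarray(vec, dtype=float)
        return out


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def scaled_nucleus_radius(n_beads: int) -> float:
    """Confinement radius for a nucleolus-only chain.

    Scales the nuclear volume with the simulated bead fraction, calibrated
    (factor 14) so that crosslink-driven condensation yields several
    discrete clusters separated by gaps wider than the community-detection
    distance threshold, as in the full-genome reference morphology."""
    return 1000.0 * (14.0 * n_beads / _N_GENOME_BEADS) ** (1.0 / 3.0)


def nucleolus_preset(n_beads: int = 250,
                     n_interior_anchors: int | None = None,
                     orientation_seed: int | None = None) -> GenomeTopology:
    """Desk-scale surrogate for the nucleolus: a single chain draped along
    the nuclear envelope with every interior bead crosslink-competent.

    Besides the two chain-end tethers, ``n_interior_anchors`` evenly spaced
    beads are anchored to the envelope along a great circle, emulating the
    membrane association of the rDNA crescent (CLIP/cohibin-like
    tethering).  The anchors partition the chain into envelope-pinned
    segments, so crosslink-driven condensation produces several discrete
    clusters rather than one consolidated globule.  The two end beads are
    excluded from the nucleolar mask; interior anchor beads remain
    crosslink-competent (they are pinned but may hold a link).

    ``orientation_seed`` draws the anchor *placement* at random (well
    separated directions on the sphere) instead of the canonical evenly
    spaced ring, emulating cell-to-cell variation in where the rDNA
    touches the envelope.  Replicate populations must not share anchor
    geometry: pairwise distances are rotation invariant, so only varied
    placement lets population averaging smear inter-cluster structure.
    """
    if n_beads < 3:
        raise ValueError("nucleolus preset needs at least 3 beads")
    if n_interior_anchors is None:
        # one anchor per ~16 beads keeps anchor spans reachable on short
        # chains while partitioning long ones into cluster-sized segments
        n_interior_anchors = max(0, min(15, n_beads // 16))
    total = n_interior_anchors + 2
    # canonical layout: anchors march along a great circle (short chains
    # get a small arc so the end tethers stay mutually reachable)
    step = 2.0 * math.pi / max(total, 4)
    angles = [k * step for k in range(total)]
    dirs = [_unit([math.sin(a), 0.0, math.cos(a)]) for a in angles]
    anchor_beads = [round(k * (n_beads - 1) / (total - 1))
                    for k in range(total)]
    if orientation_seed is not None:
        rng = np.random.default_rng(orientation_seed)
        min_cos = math.cos(0.8 * step)
        placed = []
        while len(placed) < total:
            v = _unit(rng.normal(size=3))
            if all(float(v @ u) < min_cos for u in placed):
                placed.append(v)
        # chain order visits anchors along a nearest-neighbor tour so
        # consecutive anchor spans stay short
        tour = [placed.pop(0)]
        while placed:
            last = tour[-1]
            nxt = max(range(len(placed)), key=lambda k: float(placed[k] @ last))
            tour.append(placed.pop(nxt))
        dirs = tour
        if n_interior_anchors > 0:
            # jitter which beads are anchored (segment lengths vary from
            # cell to cell); normalized cumulative gaps keep the span of
            # the chain and a minimum segment of 5 beads
            gaps = rng.uniform(0.6, 1.4, size=total - 1)
            cum = np.concatenate([[0.0], np.cumsum(gaps)]) / gaps.sum()
            interior = sorted(set(
                int(np.clip(round(f * (n_beads - 1)), 5, n_beads - 6))
                for f in cum[1:-1]))
            anchor_beads = [0] + interior + [n_beads - 1]
            dirs = dirs[: len(anchor_beads)]
    extra = [(b, d) for b, d in zip(anchor_beads[1:-1], dirs[1:-1])]
    mask = np.ones(n_beads, dtype=bool)
    mask[0] = mask[-1] = False
    return GenomeTopology(
        n_beads=n_beads,
        chains=[(0, n_beads - 1, dirs[0], dirs[-1])],
        nucleolar_mask=mask,
        extra_tethers=extra,
    )


# Approximate S. cerevisiae chromosome arm lengths in kb (left arm = start
# to centromere, right arm = centromere to end), used only to apportion
# beads between the 32 arms of the full-genome preset.
_CHROMOSOME_KB = [
    (230, 151), (813, 238), (317, 114), (1532, 450), (577, 152),
    (270, 149), (1091, 497), (563, 105), (440, 356), (746, 436),
    (667, 440), (1078, 151), (924, 268), (784, 629), (1091, 327),
    (948, 556),
]
_N_GENOME_BEADS = 2803
_N_NUCLEOLAR_BEADS = 361
_NUCLEOLUS_CHROMOSOME = 11  # chromosome XII (0-based), right arm


def _telomere_sites() -> np.ndarray:
    """Six fixed telomere anchor directions, away from the centromere pole."""
    sites = []
    for k in range(6):
        phi = 2.0 * math.pi * k / 6.0
        theta = math.radians(125.0)
        sites.append(
            [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
        )
    return np.asarray(sites)


def _centromere_sites(n: int) -> np.ndarray:
    """Centromere anchors clustered in a polar cap (spindle-pole side)."""
    sites = []
    for k in range(n):
        phi = 2.0 * math.pi * k * 0.381966  # golden-angle spacing
        theta = math.radians(5.0 + 15.0 * (k / max(n - 1, 1)))
        sites.append(
            [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
        )
    return np.asarray(sites)


def genome_preset() -> GenomeTopology:
    """Full budding-yeast genome: 2803 beads on 32 wall-tethered arms with a
    contiguous 361-bead nucleolus on the right arm of chromosome XII."""
    arm_kb = []
    for total, cen in _CHROMOSOME_KB:
        arm_kb.append(cen)          # left arm
        arm_kb.append(total - cen)  # right arm
    raw = np.maximum(2, np.round(np.asarray(arm_kb, dtype=float) / 5.0).astype(int))
    target = _N_GENOME_BEADS - _N_NUCLEOLAR_BEADS
    raw = np.maximum(2, np.round(raw * target / raw.sum()).astype(int))
    # absorb the rounding residue in the largest arm
    raw[np.argmax(raw)] += target - raw.sum()
    # the nucleolus sits mid-way along chromosome XII's right arm
    nuc_arm = 2 * _NUCLEOLUS_CHROMOSOME + 1
    arm_sizes = raw.copy()
    arm_sizes[nuc_arm] += _N_NUCLEOLAR_BEADS

    cen_sites = _centromere_sites(16)
    tel_sites = _telomere_sites()
    chains = []
    mask = np.zeros(arm_sizes.sum(), dtype=bool)
    start = 0
    for arm in range(32):
        chrom = arm // 2
        first, last = start, start + arm_sizes[arm] - 1
        cen_dir = cen_sites[chrom]
        tel_dir = tel_sites[arm % 6]
        if arm % 2 == 0:  # left arm runs telomere -> centromere
            chains.append((first, last, tel_dir, cen_dir))
        else:
            chains.append((first, last, cen_dir, tel_dir))
        if arm == nuc_arm:
            offset = (arm_sizes[arm] - _N_NUCLEOLAR_BEADS) // 2
            mask[first + offset : first + offset + _N_NUCLEOLAR_BEADS] = True
        start = last + 1
    topo = GenomeTopology(n_beads=int(arm_sizes.sum()), chains=chains, nucleolar_mask=mask)
    assert topo.n_beads == _N_GENOME_BEADS
    return topo


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Physical and numerical parameters of a simulation.

    Lengths are in nm, times in seconds.  ``kT`` is expressed in
    drag-scaled units (nm^2/s when ``drag_coefficient`` is 1), so the free
    diffusivity is ``D = kT / drag``; the default gives a free bead a
    mean-squared displacement of (100 nm)^2 per 0.1 s.  The on/off duration
    distributions default to the N(mu, (mu/5)^2) / N(mu/9, (mu/45)^2)
    kinetics; draws are truncated below at ``dt``.
    """

    mu: float
    total_time: float
    on_mean: float | None = None
    on_sd: float | None = None
    off_mean: float | None = None
    off_sd: float | None = None
    d_link: float = 90.0
    nucleus_radius: float = 1000.0
    dt: float = 1e-4
    save_interval: float = 0.1
    contour_length: float = 200.0       # WLC spring contour length L0
    persistence_length: float = 50.0    # backbone spring prefactor kT / Lp
    link_persistence_length: float = 3.0  # crosslink spring scale (stiffer)
    kT: float = 16667.0
    drag_coefficient: float = 1.0
    repulsion_radius: float = 30.0      # soft-core radius a; overlap below 2a
    repulsion_strength: float = 6.0     # soft push-back per nm of overlap
    wall_strength: float = 200.0        # inward restoring force per nm outside
    match_policy: str = "random"        # "random" | "greedy" pair matching
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.on_mean is None:
            self.on_mean = self.mu
        if self.on_sd is None:
            self.on_sd = self.mu / 5.0
        if self.off_mean is None:
            self.off_mean = self.mu / 9.0
        if self.off_sd is None:
            self.off_sd = self.mu / 45.0
        if self.d_link <= 0 or self.nucleus_radius <= 0:
            raise ValueError("length scales must be positive")
        if not self.dt < self.save_interval:
            raise ValueError("dt must be smaller than save_interval")
        for name in ("contour_length", "persistence_length", "repulsion_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.match_policy not in ("random", "greedy"):
            raise ValueError("match_policy must be 'random' or 'greedy'")

    @property
    def diffusivity(self) -> float:
        return self.kT / self.drag_coefficient

    @property
    def spring_prefactor(self) -> float:
        return self.kT / self.persistence_length

    @property
    def link_spring_prefactor(self) -> float:
        return self.kT / self.link_persistence_length

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimState:
    """Instantaneous simulator state."""

    positions: np.ndarray          # (N, 3) nm
    active: np.ndarray             # (N,) bool; meaningful for nucleolar beads
    state_timer: np.ndarray        # (N,) s remaining in the current state
    link_partner: np.ndarray       # (N,) partner index or -1
    t: float = 0.0

    @property
    def links(self) -> set:
        """Current crosslinks as a set of sorted bead-index pairs."""
        out = set()
        for i, j in enumerate(self.link_partner):
            if j >= 0 and i < j:
                out.add((i, int(j)))
        return out

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(), self.active.copy(),
            self.state_timer.copy(), self.link_partner.copy(), self.t,
        )


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

_X_CAP = 0.95       # backbone extension ratio where the force saturates
_X_CAP_LINK = 0.50  # crosslink cap (stiffer spring, lower saturation)


@njit(cache=True, fastmath=True)
def _wlc_force_mag(r, L0, fpref, xcap):
    """Marko-Siggia interpolation force magnitude (attractive, toward zero
    extension), with the divergence capped at extension ratio ``xcap``."""
    x = r / L0
    if x > xcap:
        x = xcap
    return fpref * (0.25 / ((1.0 - x) * (1.0 - x)) - 0.25 + x)


@njit(cache=True, fastmath=True)
def _accum_pair_forces(F, pos, bonds, n_bonds, L0, fpref):
    for b in range(n_bonds):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        f = _wlc_force_mag(r, L0, fpref, _X_CAP) / r
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz


@njit(cache=True, fastmath=True)
def _accum_link_forces(F, pos, partner, L0, fpref):
    n = pos.shape[0]
    for i in range(n):
        j = partner[i]
        if j > i:
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                continue
            f = _wlc_force_mag(r, L0, fpref, _X_CAP_LINK) / r
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz


@njit(cache=True, fastmath=True)
def _accum_repulsion(F, pos, pairs, n_pairs, contact, k_rep):
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < contact and r > 1e-12:
            overlap = contact - r
            if overlap > 0.5 * contact:  # cap: deep overlaps (start-up only)
                overlap = 0.5 * contact
            f = k_rep * overlap / r
            F[i, 0] -= f * dx
            F[i, 1] -= f * dy
            F[i, 2] -= f * dz
            F[j, 0] += f * dx
            F[j, 1] += f * dy
            F[j, 2] += f * dz


@njit(cache=True, fastmath=True)
def _accum_wall(F, pos, tethered, R, k_wall):
    n = pos.shape[0]
    for i in range(n):
        if tethered[i]:
            continue
        r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r > R:
            f = k_wall * (r - R) / r
            F[i, 0] -= f * pos[i, 0]
            F[i, 1] -= f * pos[i, 1]
            F[i, 2] -= f * pos[i, 2]


@njit(cache=True, fastmath=True)
def _all_pairs_within(pos, cutoff, pairs):
    """Brute-force neighbor-list build; returns pair count or -1 on overflow."""
    n = pos.shape[0]
    cap = pairs.shape[0]
    c2 = cutoff * cutoff
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                if m >= cap:
                    return -1
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return m


@njit(cache=True)
def _draw_duration(mean, sd, dt):
    d = mean + sd * np.random.randn()
    if d < dt:
        d = dt
    return d


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _match_candidates(pos, cand, n_cand, partner, taken, policy):
    """Link candidate pairs one-to-one (each bead used once).

    ``policy`` 0 pairs candidates in uniformly random order (the default:
    any in-range active pair is equally likely to bind, which lets
    crosslinks staple chain loops rather than always the closest
    neighbor); ``policy`` 1 pairs greedily in ascending distance order
    with a deterministic (i, j) tie-break.  Returns the number of links
    formed, with the formed pairs moved to the front of ``cand`` (in
    acceptance order).
    """
    if n_cand == 0:
        return 0
    order = np.arange(n_cand)
    if policy == 0:
        for a in range(n_cand - 1, 0, -1):  # Fisher-Yates
            b = np.random.randint(0, a + 1)
            tmp = order[a]
            order[a] = order[b]
            order[b] = tmp
    else:
        d = np.empty(n_cand)
        for p in range(n_cand):
            i = cand[p, 0]
            j = cand[p, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d[p] = math.sqrt(dx * dx + dy * dy + dz * dz)
        order = np.argsort(d)
        # stable (i, j) ordering within exact distance ties
        for a in range(1, n_cand):
            b = a
            while b > 0 and d[order[b - 1]] == d[order[b]] and (
                cand[order[b - 1], 0] > cand[order[b], 0]
                or (cand[order[b - 1], 0] == cand[order[b], 0]
                    and cand[order[b - 1], 1] > cand[order[b], 1])
            ):
                tmp = order[b - 1]
                order[b - 1] = order[b]
                order[b] = tmp
                b -= 1
    n_formed = 0
    for a in range(n_cand):
        p = order[a]
        i = cand[p, 0]
        j = cand[p, 1]
        if taken[i] or taken[j]:
            continue
        taken[i] = True
        taken[j] = True
        partner[i] = j
        partner[j] = i
        cand[n_formed, 0] = i
        cand[n_formed, 1] = j
        n_formed += 1
    return n_formed


@njit(cache=True, fastmath=True)
def _advance_chunk(
    pos, tethered, chain_id, nucleolar, active, timer, partner,
    bonds, n_steps, t0,
    dt, D, drag, R, L0, fpref, fpref_link, contact, k_rep, k_wall, d_link,
    on_mean, on_sd, off_mean, off_sd,
    nl_pairs, nl_meta, nl_cutoff, nl_skin, disp_acc, max_disp,
    xi, form_buf, break_buf, dur_buf, counts, match_policy,
):
    """Advance ``n_steps`` integrator steps, logging crosslink and
    activity-duration events into the preallocated buffers.

    ``xi`` is the (n_steps, n, 3) array of pre-drawn standard normals for
    the thermal kicks (bulk generation outside the kernel is much faster
    than per-call draws).  Returns a status code: 0 ok, 1 neighbor-list
    overflow, 2 event-buffer overflow, 3 stability bound violated, 4
    non-finite positions.  counts holds (n_form, n_break, n_dur,
    steps_done) on exit; nl_meta carries (n_pairs, max accumulated
    displacement) across chunks.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    cand = np.empty((n * 8, 2), dtype=np.int64)
    taken = np.zeros(n, dtype=np.bool_)
    n_form = 0
    n_break = 0
    n_dur = 0
    noise = math.sqrt(2.0 * D * dt)

    for step in range(n_steps):
        t = t0 + step * dt

        # --- neighbor list upkeep
        if nl_meta[1] > 0.5 * nl_skin or nl_meta[0] < 0:
            m = _all_pairs_within(pos, nl_cutoff, nl_pairs)
            if m < 0:
                # nothing in this step has been applied yet; the caller can
                # enlarge the pair array and resume from this step
                counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
                counts[3] = step
                return 1
            nl_meta[0] = m
            nl_meta[1] = 0.0
            for i in range(n):
                disp_acc[i] = 0.0
        n_pairs = int(nl_meta[0])

        # --- forces
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        _accum_pair_forces(F, pos, bonds, bonds.shape[0], L0, fpref)
        _accum_link_forces(F, pos, partner, L0, fpref_link)
        _accum_repulsion(F, pos, nl_pairs, n_pairs, contact, k_rep)
        _accum_wall(F, pos, tethered, R, k_wall)

        # --- Euler-Maruyama step with wall projection
        step_max = 0.0
        for i in range(n):
            if tethered[i]:
                continue
            dx = F[i, 0] / drag * dt + noise * xi[step, i, 0]
            dy = F[i, 1] / drag * dt + noise * xi[step, i, 1]
            dz = F[i, 2] / drag * dt + noise * xi[step, i, 2]
            disp = math.sqrt(dx * dx + dy * dy + dz * dz)
            if disp > step_max:
                step_max = disp
            disp_acc[i] += disp
            if disp_acc[i] > nl_meta[1]:
                nl_meta[1] = disp_acc[i]
            pos[i, 0] += dx
            pos[i, 1] += dy
            pos[i, 2] += dz
            r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r > R:
                s = R / r
                pos[i, 0] *= s
                pos[i, 1] *= s
                pos[i, 2] *= s
        if not math.isfinite(step_max):
            counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
            return 4
        if step_max > max_disp:
            counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
            counts[3] = step
            return 3

        # --- activity kinetics (nucleolar beads only)
        for i in range(n):
            if not nucleolar[i]:
                continue
            timer[i] -= dt
            if timer[i] <= 0.0:
                if active[i]:
                    active[i] = False
                    timer[i] = _draw_duration(off_mean, off_sd, dt)
                    if n_dur >= dur_buf.shape[0]:
                        counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
                        return 2
                    dur_buf[n_dur, 0] = i
                    dur_buf[n_dur, 1] = 0.0  # entering inactive state
                    dur_buf[n_dur, 2] = timer[i]
                    n_dur += 1
                    j = partner[i]
                    if j >= 0:
                        partner[i] = -1
                        partner[j] = -1
                        if n_break >= break_buf.shape[0]:
                            counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
                            return 2
                        if i < j:
                            break_buf[n_break, 0] = i
                            break_buf[n_break, 1] = j
                        else:
                            break_buf[n_break, 0] = j
                            break_buf[n_break, 1] = i
                        break_buf[n_break, 2] = t + dt
                        n_break += 1
                else:
                    active[i] = True
                    timer[i] = _draw_duration(on_mean, on_sd, dt)
                    if n_dur >= dur_buf.shape[0]:
                        counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
                        return 2
                    dur_buf[n_dur, 0] = i
                    dur_buf[n_dur, 1] = 1.0  # entering active state
                    dur_buf[n_dur, 2] = timer[i]
                    n_dur += 1

        # --- crosslink matching among unlinked active nucleolar beads
        n_cand = 0
        d2 = d_link * d_link
        for p in range(n_pairs):
            i = nl_pairs[p, 0]
            j = nl_pairs[p, 1]
            if not (nucleolar[i] and nucleolar[j]):
                continue
            if not (active[i] and active[j]):
                continue
            if partner[i] >= 0 or partner[j] >= 0:
                continue
            if chain_id[i] == chain_id[j] and abs(i - j) == 1:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < d2:
                if n_cand >= cand.shape[0]:
                    break
                cand[n_cand, 0] = i
                cand[n_cand, 1] = j
                n_cand += 1
        if n_cand > 0:
            for i in range(n):
                taken[i] = partner[i] >= 0
            n_new = _match_candidates(pos, cand, n_cand, partner, taken,
                                      match_policy)
            for a in range(n_new):
                if n_form >= form_buf.shape[0]:
                    counts[0] = n_form; counts[1] = n_break; counts[2] = n_dur
                    return 2
                form_buf[n_form, 0] = cand[a, 0]
                form_buf[n_form, 1] = cand[a, 1]
                form_buf[n_form, 2] = t + dt
                n_form += 1

    counts[0] = n_form
    counts[1] = n_break
    counts[2] = n_dur
    counts[3] = n_steps
    return 0


# ---------------------------------------------------------------------------
# Python-level operations
# ---------------------------------------------------------------------------

def init_configuration(topology: GenomeTopology, params: SimParams,
                       rng_seed: int | None = None) -> SimState:
    """Place chains inside the nucleus and draw initial activity states.

    Chain ends with tether sites are pinned on the envelope; interior beads
    follow a Brownian-bridge random walk between the anchors (or a free
    walk from a random interior point for untethered chains), radially
    clamped inside the sphere.  Activity states start from the stationary
    occupancy mu/(mu + mu/9); timers get a uniform residual of a freshly
    drawn duration.
    """
    if rng_seed is None:
        rng_seed = params.seed
    rng = np.random.default_rng(rng_seed)
    R = params.nucleus_radius
    L0 = params.contour_length
    pos = np.empty((topology.n_beads, 3))
    anchors = topology.tether_positions(R)

    tethered_mask = topology.tethered
    for first, last, t0, t1 in topology.chains:
        n = last - first + 1
        # anchored waypoints along this chain (ends and interior anchors)
        waypoints = [(i, anchors[i]) for i in range(first, last + 1)
                     if i in anchors]
        if not waypoints:
            p0 = rng.uniform(-R / 2, R / 2, size=3)
            waypoints = [(first, p0), (last, p0)]
        if waypoints[0][0] != first:
            waypoints.insert(0, (first, waypoints[0][1]))
        if waypoints[-1][0] != last:
            waypoints.append((last, waypoints[-1][1]))
        for (i0, p0), (i1, p1) in zip(waypoints, waypoints[1:]):
            span = float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
            if i1 > i0 and span > (i1 - i0) * L0:
                raise ConfigurationError(
                    f"beads ({i0}, {i1}): anchor span {span:.0f} nm exceeds "
                    f"contour {(i1 - i0) * L0:.0f} nm")
        if n == 1:
            pos[first] = waypoints[0][1]
            continue
        sigma = min(60.0, 0.45 * L0 / math.sqrt(3.0))
        for _ in range(12):
            xyz = np.empty((n, 3))
            for (i0, p0), (i1, p1) in zip(waypoints, waypoints[1:]):
                m = i1 - i0 + 1
                if m == 1:
                    xyz[i0 - first] = p0
                    continue
                base = np.linspace(p0, p1, m)
                steps = rng.normal(0.0, sigma, size=(m - 1, 3))
                walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
                frac = np.linspace(0.0, 1.0, m)[:, None]
                xyz[i0 - first : i1 - first + 1] = \
                    base + walk - frac * walk[-1]
            # clamp unanchored beads inside the sphere
            rr = np.linalg.norm(xyz, axis=1)
            over = (rr > 0.98 * R) & ~tethered_mask[first : last + 1]
            xyz[over] *= (0.98 * R / rr[over])[:, None]
            seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            if seg.max() < 0.9 * L0:
                break
            sigma *= 0.6
        else:
            raise ConfigurationError(
                f"chain ({first}, {last}) cannot be laid out within the nucleus"
            )
        pos[first : last + 1] = xyz

    _relax_overlaps(pos, topology, params)

    n = topology.n_beads
    active = np.zeros(n, dtype=bool)
    timer = np.full(n, np.inf)
    p_on = params.on_mean / (params.on_mean + params.off_mean)
    nuc = np.flatnonzero(topology.nucleolar_mask)
    for i in nuc:
        if rng.random() < p_on:
            active[i] = True
            dur = max(params.dt, rng.normal(params.on_mean, params.on_sd))
        else:
            dur = max(params.dt, rng.normal(params.off_mean, params.off_sd))
        timer[i] = rng.random() * dur
    partner = np.full(n, -1, dtype=np.int64)
    return SimState(pos, active, timer, partner, 0.0)


def _relax_overlaps(pos: np.ndarray, topology: GenomeTopology,
                    params: SimParams, n_iter: int = 400,
                    max_step: float = 4.0) -> None:
    """Deterministic descent removing deep excluded-volume overlaps from a
    freshly laid-out configuration (displacements clamped to ``max_step``
    nm per iteration; tethered beads pinned, confinement enforced)."""
    n = pos.shape[0]
    bonds = topology.bonds
    tethered = topology.tethered
    contact = 2.0 * params.repulsion_radius
    pairs = np.empty((n * 8, 2), dtype=np.int64)
    eta = max_step / max(params.repulsion_strength * contact / 2.0, 1e-9)
    for _ in range(n_iter):
        F = np.zeros((n, 3))
        m = _all_pairs_within(pos, contact, pairs)
        if m < 0:
            pairs = np.empty((pairs.shape[0] * 2, 2), dtype=np.int64)
            continue
        if m == 0:
            break
        _accum_repulsion(F, pos, pairs, m, contact, params.repulsion_strength)
        _accum_pair_forces(F, pos, bonds, bonds.shape[0],
                           params.contour_length, params.spring_prefactor)
        step = F * eta
        norms = np.linalg.norm(step, axis=1)
        over = norms > max_step
        step[over] *= (max_step / norms[over])[:, None]
        step[tethered] = 0.0
        pos += step
        r = np.linalg.norm(pos, axis=1)
        out = (r > params.nucleus_radius) & ~tethered
        pos[out] *= (params.nucleus_radius / r[out])[:, None]


def compute_forces(state: SimState, topology: GenomeTopology,
                   params: SimParams) -> np.ndarray:
    """Total deterministic force on every bead: WLC backbone and crosslink
    springs, soft pairwise repulsion, and the inward wall restoring force.
    Newton's-third-law symmetric by construction."""
    pos = np.ascontiguousarray(state.positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise FloatingPointError("non-finite bead positions")
    n = pos.shape[0]
    F = np.zeros((n, 3))
    bonds = topology.bonds
    _accum_pair_forces(F, pos, bonds, bonds.shape[0], params.contour_length,
                       params.spring_prefactor)
    _accum_link_forces(F, pos, state.link_partner, params.contour_length,
                       params.link_spring_prefactor)
    contact = 2.0 * params.repulsion_radius
    pairs = np.empty((n * (n - 1) // 2, 2), dtype=np.int64)
    m = _all_pairs_within(pos, contact, pairs)
    _accum_repulsion(F, pos, pairs, m, contact, params.repulsion_strength)
    _accum_wall(F, pos, topology.tethered, params.nucleus_radius,
                params.wall_strength)
    return F


def step_dynamics(state: SimState, topology: GenomeTopology, params: SimParams,
                  rng: np.random.Generator) -> SimState:
    """One overdamped Euler-Maruyama step with post-step wall projection.
    Tethered beads do not move.  Raises StabilityError when any bead moves
    farther than half the repulsion radius in a single step."""
    out = state.copy()
    F = compute_forces(state, topology, params)
    dt = params.dt
    noise = math.sqrt(2.0 * params.diffusivity * dt)
    xi = rng.standard_normal(size=out.positions.shape)
    disp = F / params.drag_coefficient * dt + noise * xi
    disp[topology.tethered] = 0.0
    step_max = float(np.linalg.norm(disp, axis=1).max()) if len(disp) else 0.0
    if step_max > params.repulsion_radius / 2.0:
        raise StabilityError(
            f"step displacement {step_max:.2f} nm exceeds "
            f"{params.repulsion_radius / 2:.2f} nm at t={state.t:.4f}s"
        )
    out.positions = out.positions + disp
    r = np.linalg.norm(out.positions, axis=1)
    over = (r > params.nucleus_radius) & ~topology.tethered
    out.positions[over] *= (params.nucleus_radius / r[over])[:, None]
    out.t = state.t + dt
    return out


def update_activity(state: SimState, params: SimParams,
                    rng: np.random.Generator, dt: float | None = None,
                    nucleolar_mask: np.ndarray | None = None) -> tuple:
    """Decrement activity timers by ``dt``; flip expired states, drawing the
    next duration from the opposite distribution (truncated below at the
    integrator step).  Links whose endpoint inactivates are removed.

    Returns ``(new_state, broken_links)``.
    """
    if dt is None:
        dt = params.dt
    out = state.copy()
    n = out.positions.shape[0]
    if nucleolar_mask is None:
        nucleolar_mask = np.isfinite(out.state_timer)
    broken = []
    for i in range(n):
        if not nucleolar_mask[i]:
            continue
        out.state_timer[i] -= dt
        if out.state_timer[i] <= 0.0:
            if out.active[i]:
                out.active[i] = False
                out.state_timer[i] = max(
                    params.dt, rng.normal(params.off_mean, params.off_sd))
                j = out.link_partner[i]
                if j >= 0:
                    out.link_partner[i] = -1
                    out.link_partner[j] = -1
                    broken.append((min(i, int(j)), max(i, int(j))))
            else:
                out.active[i] = True
                out.state_timer[i] = max(
                    params.dt, rng.normal(params.on_mean, params.on_sd))
    return out, broken


def match_crosslinks(state: SimState, topology: GenomeTopology,
                     params: SimParams,
                     rng: np.random.Generator | None = None) -> tuple:
    """Form new crosslinks among unlinked, active, non-adjacent nucleolar
    bead pairs closer than ``d_link``; each bead is used at most once and
    existing links persist.

    With ``params.match_policy == "random"`` (default) eligible pairs are
    taken in uniformly random order drawn from ``rng``; with ``"greedy"``
    they are taken in ascending distance order with an (i, j) index
    tie-break.  Returns ``(new_state, formed_pairs)``.
    """
    out = state.copy()
    pos = np.ascontiguousarray(out.positions, dtype=float)
    n = pos.shape[0]
    nuc = topology.nucleolar_mask
    cid = topology.chain_id
    cand = []
    for i in range(n):
        if not nuc[i] or not out.active[i] or out.link_partner[i] >= 0:
            continue
        for j in range(i + 1, n):
            if not nuc[j] or not out.active[j] or out.link_partner[j] >= 0:
                continue
            if cid[i] == cid[j] and j - i == 1:
                continue
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d < params.d_link:
                cand.append((d, i, j))
    if params.match_policy == "greedy":
        cand.sort()
    else:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        cand = [cand[k] for k in rng.permutation(len(cand))]
    formed = []
    for _, i, j in cand:
        if out.link_partner[i] >= 0 or out.link_partner[j] >= 0:
            continue
        out.link_partner[i] = j
        out.link_partner[j] = i
        formed.append((i, j))
    return out, formed


# ---------------------------------------------------------------------------
# Trajectory container and the main simulation loop
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Saved time series of a simulation.

    ``positions`` is (T, N, 3) in nm on the regular grid ``times`` (every
    ``save_interval``, frame 0 = initial configuration).  ``link_log`` rows
    are ``(bead_i, bead_j, t_formed, t_broken)``; links still closed at the
    end of the run are reported with ``t_broken`` equal to the final time.
    ``activity_log`` rows are ``(bead, entering_active, drawn_duration)``.
    """

    times: np.ndarray
    positions: np.ndarray
    topology: GenomeTopology
    params: SimParams
    link_log: np.ndarray
    activity_log: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def nucleolar_positions(self) -> np.ndarray:
        return self.positions[:, self.topology.nucleolar_mask, :]

    def frame_index(self, t: float) -> int:
        idx = int(round(t / self.params.save_interval))
        if idx < 0 or idx >= self.n_frames or not math.isclose(
                self.times[idx], t, rel_tol=0.0, abs_tol=1e-9 + 1e-6 * self.params.save_interval):
            raise KeyError(f"t={t} is not on the saved time grid")
        return idx

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write the trajectory to an HDF5 file with named datasets."""
        import h5py
        import json

        with h5py.File(path, "w") as h5:
            h5.create_dataset("times", data=self.times)
            h5.create_dataset("positions", data=self.positions,
                              chunks=(min(64, self.n_frames),
                                      self.positions.shape[1], 3),
                              compression="gzip", compression_opts=1)
            h5.create_dataset("nucleolar_mask",
                              data=self.topology.nucleolar_mask)
            h5.create_dataset("link_log", data=self.link_log)
            if self.activity_log is not None:
                h5.create_dataset("activity_log", data=self.activity_log)
            chains = [(int(f), int(l),
                       list(map(float, t0)) if t0 is not None else None,
                       list(map(float, t1)) if t1 is not None else None)
                      for f, l, t0, t1 in self.topology.chains]
            h5.attrs["chains"] = json.dumps(chains)
            h5.attrs["bead_bp"] = self.topology.bead_bp
            h5.attrs["params"] = json.dumps(self.params.to_dict())

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py
        import json

        with h5py.File(path, "r") as h5:
            times = h5["times"][:]
            positions = h5["positions"][:]
            mask = h5["nucleolar_mask"][:].astype(bool)
            link_log = h5["link_log"][:]
            activity = h5["activity_log"][:] if "activity_log" in h5 else None
            chains = [
                (f, l,
                 np.asarray(t0) if t0 is not None else None,
                 np.asarray(t1) if t1 is not None else None)
                for f, l, t0, t1 in json.loads(h5.attrs["chains"])
            ]
            params = SimParams(**json.loads(h5.attrs["params"]))
            topo = GenomeTopology(n_beads=positions.shape[1], chains=chains,
                                  nucleolar_mask=mask,
                                  bead_bp=int(h5.attrs["bead_bp"]))
        return cls(times, positions, topo, params, link_log, activity)

    def export_positions_csv(self, path, frame: int | None = None) -> None:
        """Plain CSV export (frame, bead, x, y, z) for interoperability."""
        frames = range(self.n_frames) if frame is None else [frame]
        with open(path, "w") as fh:
            fh.write("frame,bead,x_nm,y_nm,z_nm\n")
            for f in frames:
                for b in range(self.positions.shape[1]):
                    x, y, z = self.positions[f, b]
                    fh.write(f"{f},{b},{x:.3f},{y:.3f},{z:.3f}\n")


def simulate(topology: GenomeTopology, params: SimParams,
             log_activity: bool = True,
             initial_state: SimState | None = None) -> Trajectory:
    """Run the full Brownian-dynamics / crosslink-kinetics loop.

    Snapshots are stored every ``save_interval`` seconds (frame 0 is the
    initial configuration, drawn by ``init_configuration`` unless an
    explicit ``initial_state`` is supplied); the run is fully reproducible
    from ``params.seed``.
    """
    state = (initial_state.copy() if initial_state is not None
             else init_configuration(topology, params, params.seed))
    n = topology.n_beads
    steps_per_frame = int(round(params.save_interval / params.dt))
    n_frames = int(round(params.total_time / params.save_interval)) + 1

    pos = np.ascontiguousarray(state.positions)
    tethered = topology.tethered
    chain_id = topology.chain_id
    nucleolar = topology.nucleolar_mask
    active = state.active.copy()
    timer = np.where(np.isfinite(state.state_timer), state.state_timer, 1e30)
    partner = state.link_partner.copy()
    bonds = topology.bonds

    contact = 2.0 * params.repulsion_radius
    nl_skin = 40.0
    nl_cutoff = max(contact, params.d_link) + nl_skin
    nl_cap = 64 * n
    nl_pairs = np.empty((nl_cap, 2), dtype=np.int64)
    nl_meta = np.array([-1.0, 0.0])
    disp_acc = np.zeros(n)
    max_disp = params.repulsion_radius / 2.0

    # worst realistic case: every nucleolar bead cycles ~save_interval/off_mean
    # times per chunk; pad generously so overflow is a hard error, not a retry
    cycles = params.save_interval / max(params.off_mean, params.dt)
    buf_cap = int(4 * n * max(4.0, cycles)) + 1024
    form_buf = np.empty((buf_cap, 3))
    break_buf = np.empty((buf_cap, 3))
    dur_buf = np.empty((buf_cap, 3))
    counts = np.zeros(4, dtype=np.int64)

    _seed_numba(params.seed % (2**31 - 1))
    noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    match_policy = 0 if params.match_policy == "random" else 1

    times = np.arange(n_frames) * params.save_interval
    traj_pos = np.empty((n_frames, n, 3))
    traj_pos[0] = pos
    open_links: dict = {}
    closed = []
    durations = []

    def _drain():
        # merge the two event streams in time order (a pair can break and
        # re-form within one chunk)
        events = [(form_buf[k, 2], 1, int(form_buf[k, 0]), int(form_buf[k, 1]))
                  for k in range(counts[0])]
        events += [(break_buf[k, 2], 0, int(break_buf[k, 0]),
                    int(break_buf[k, 1])) for k in range(counts[1])]
        events.sort()
        for t, kind, i, j in events:
            key = (min(i, j), max(i, j))
            if kind == 1:
                open_links[key] = t
            else:
                t_on = open_links.pop(key, None)
                if t_on is not None:
                    closed.append((key[0], key[1], t_on, t))
        if log_activity and counts[2]:
            durations.append(dur_buf[: counts[2]].copy())

    for f in range(1, n_frames):
        remaining = steps_per_frame
        t_chunk = times[f - 1]
        xi = noise_rng.standard_normal((steps_per_frame, n, 3))
        while remaining > 0:
            status = _advance_chunk(
                pos, tethered, chain_id, nucleolar, active, timer, partner,
                bonds, remaining, t_chunk,
                params.dt, params.diffusivity, params.drag_coefficient,
                params.nucleus_radius, params.contour_length,
                params.spring_prefactor, params.link_spring_prefactor,
                contact, params.repulsion_strength,
                params.wall_strength, params.d_link,
                params.on_mean, params.on_sd, params.off_mean, params.off_sd,
                nl_pairs, nl_meta, nl_cutoff, nl_skin, disp_acc, max_disp,
                xi[steps_per_frame - remaining :], form_buf, break_buf,
                dur_buf, counts, match_policy,
            )
            _drain()
            if status == 1:
                remaining -= int(counts[3])
                t_chunk += counts[3] * params.dt
                nl_cap *= 2
                nl_pairs = np.empty((nl_cap, 2), dtype=np.int64)
                nl_meta[0] = -1.0
                continue
            if status == 2:
                raise RuntimeError(
                    f"event buffer overflow near t={t_chunk:.4f}s")
            if status == 3:
                t_fail = t_chunk + counts[3] * params.dt
                raise StabilityError(
                    f"displacement bound exceeded at t={t_fail:.4f}s")
            if status == 4:
                raise FloatingPointError(
                    f"non-finite positions near t={t_chunk:.4f}s")
            remaining = 0
        traj_pos[f] = pos

    t_end = times[-1]
    for (i, j), t_on in sorted(open_links.items()):
        closed.append((i, j, t_on, max(t_end, t_on + params.dt)))
    link_log = np.asarray(sorted(closed, key=lambda r: (r[2], r[0], r[1])),
                          dtype=float).reshape(-1, 4)
    activity_log = (np.vstack(durations) if log_activity and durations
                    else None)
    return Trajectory(times, traj_pos, topology, params, link_log,
                      activity_log)


def sample_state_durations(mu: float, n: int, seed: int = 0,
                           active: bool = True, dt: float = 1e-4) -> np.ndarray:
    """Draw ``n`` state durations through the simulator's own sampler:
    N(mu, (mu/5)^2) for the active state, N(mu/9, (mu/45)^2) for the
    inactive state, truncated below at ``dt``."""
    params = SimParams(mu=mu, total_time=1.0, dt=dt)
    _seed_numba(seed % (2**31 - 1))
    mean, sd = ((params.on_mean, params.on_sd) if active
                else (params.off_mean, params.off_sd))
    return np.array([_draw_duration(mean, sd, dt) for _ in range(n)])
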