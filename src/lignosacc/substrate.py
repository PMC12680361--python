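"""In-silico lignocellulose substrate.

The substrate is a coarse-grained microfibril: a hexagonally close-packed
core of parallel cellulose chains (18, 24, or 36 depending on the mode
code), wrapped in two shell layers of randomly placed hemicellulose
segments (inner shell) and lignin monolignol runs (outer shell), with
unfilled shell positions acting as gaps through which enzymes reach the
core.  Each chain is a 1-D array of monomers connected by glycosidic
bonds; bonds are crystalline or amorphous, and crystalline bonds are
digested at a rate scaled down by the digestibility ratio ``r_ca``.

Alternatively the same polymer inventory can be built as free-floating
chains (``free_floating=True``) where every bond is solvent-exposed and
lignin acts purely as a dissolved adsorber of enzymes.

:class:`SubstrateState` owns all mutable bookkeeping during a simulation:
bond states, monomer occupancy, enzyme-accessibility registries, bound
processive enzymes, and the soluble sugar pools.  All registry updates are
incremental but can be cross-checked against a from-scratch rebuild
(:meth:`SubstrateState.rebuild_registries`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace


import numpy as np

__all__ = [
    "Composition",
    "SubstrateConfig",
    "SubstrateState",
    "Chain",
    "ConfigurationError",
    "assign_crystallinity",
    "build_microfibril",
    "build_free_substrate",
    "build_substrate",
    "average_crystallinity",
    "MODE_CHAINS",
]

PRETREATMENTS = ("untreated", "NS+OCAT", "YS+OCAT", "NA")

#: number of core cellulose chains per microfibril mode code
MODE_CHAINS = {1: 24, 2: 24, 3: 18, 4: 18, 5: 36}

#: columns of the close-packed cross-section per chain count
_MODE_COLS = {18: 3, 24: 4, 36: 6}

# axial-coordinate neighbour offsets on a triangular lattice
_AX_NEIGH = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

# bounds on random hemicellulose / lignin segment lengths (monomers)
_SEG_MIN, _SEG_MAX = 10, 50
# smallest insoluble fragment: 3 monomers (1- and 2-mers are soluble)
_MIN_FRAGMENT = 3


class ConfigurationError(ValueError):
    """Invalid substrate or cocktail configuration."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Composition:
    """Mass fractions of the biomass constituents (0-1 scale).

    Fractions come from compositional assays and need not sum exactly to
    one; only the ratios to cellulose are used when building a substrate.
    The acetate fraction is carried for bookkeeping but unused.
    """

    pct_cellulose: float
    pct_hemicellulose: float = 0.0
    pct_lignin: float = 0.0
    pct_acetate: float = 0.0
    sample_id: str = ""
    pretreatment: str = "NA"

    def __post_init__(self) -> None:
        for name in ("pct_cellulose", "pct_hemicellulose", "pct_lignin", "pct_acetate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        total = (
            self.pct_cellulose
            + self.pct_hemicellulose
            + self.pct_lignin
            + self.pct_acetate
        )
        if total > 1.05:
            raise ConfigurationError(f"composition total {total:.3f} exceeds 1.05")
        if self.pretreatment not in PRETREATMENTS:
            raise ConfigurationError(f"unknown pretreatment {self.pretreatment!r}")


@dataclass(frozen=True)
class SubstrateConfig:
    """Full substrate-side parameterisation.

    ``mode_code`` selects the cross-section (3 or 4: 18 chains; 1 or 2: 24;
    5: 36).  ``length_fibril`` is the number of glycosidic bonds per core
    cellulose chain, so each chain carries ``length_fibril + 1`` monomers.
    ``CF_*`` are crystallinity fractions, ``r_ca_*`` digestibility ratios
    (crystalline relative to amorphous; 0 = indigestible, 1 = equal).
    ``mu_defect`` is the fraction of a chain's amorphous bonds embedded as
    interior defect patches and ``N_defect`` the fraction of outer chains
    carrying such patches.
    """

    composition: Composition
    mode_code: int = 3
    length_fibril: int = 200
    CF_cellu: float = 0.5
    CF_hemi: float = 0.5
    r_ca_cellu: float = 0.1
    r_ca_hemi: float = 0.1
    mu_defect: float = 0.0
    N_defect: float = 0.0
    r_monomer: float = 0.6
    lignin_adhesion_rate: float = 200.0
    free_floating: bool = False
    hemi_is_xylan: bool = True
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode_code not in MODE_CHAINS:
            raise ConfigurationError(f"unknown mode_code {self.mode_code}")
        if self.composition.pct_cellulose <= 0:
            raise ConfigurationError("pct_cellulose must be positive: substrate undefined")
        if self.length_fibril < 2:
            raise ConfigurationError("length_fibril must be >= 2 bonds")
        for name in ("CF_cellu", "CF_hemi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("r_ca_cellu", "r_ca_hemi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.mu_defect <= 0.5:
            raise ConfigurationError(f"mu_defect={self.mu_defect} outside [0, 0.5]")
        if not 0.0 <= self.N_defect <= 1.0:
            raise ConfigurationError(f"N_defect={self.N_defect} outside [0, 1]")
        if self.lignin_adhesion_rate <= 0:
            raise ConfigurationError("lignin_adhesion_rate must be positive")

    @property
    def n_chains(self) -> int:
        return MODE_CHAINS[self.mode_code]

    def with_(self, **kwargs) -> "SubstrateConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# crystallinity assignment
# ---------------------------------------------------------------------------


def assign_crystallinity(
    n_bonds: int,
    cf: float,
    mu_defect: float,
    n_defect: float,
    is_outer: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign crystalline/amorphous states to the bonds of one chain.

    Exactly ``round(cf * n_bonds)`` bonds are crystalline.  Amorphous
    bonds sit at the two chain ends (split evenly, tie to the left), except
    that outer chains selected as defective (probability ``n_defect``)
    embed a fraction ``mu_defect`` of their amorphous allotment as 1-3
    contiguous interior defect patches.

    Returns a boolean array (True = crystalline) of length ``n_bonds``.
    """
    if not 0.0 <= cf <= 1.0:
        raise ConfigurationError(f"CF={cf} outside [0, 1]")
    if n_bonds <= 0:
        return np.zeros(0, dtype=bool)
    n_cryst = int(round(cf * n_bonds))
    n_am = n_bonds - n_cryst
    cryst = np.ones(n_bonds, dtype=bool)
    if n_cryst == 0:
        cryst[:] = False
        return cryst
    if n_am == 0:
        return cryst

    defect_total = 0
    if is_outer and mu_defect > 0 and n_defect > 0 and rng.random() < n_defect:
        defect_total = int(round(mu_defect * n_am))
    end_am = n_am - defect_total
    left = (end_am + 1) // 2
    right = end_am - left
    cryst[:left] = False
    if right:
        cryst[n_bonds - right :] = False

    if defect_total > 0:
        n_patch = min(int(rng.integers(1, 4)), defect_total)
        if n_patch > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, defect_total), size=n_patch - 1, replace=False)
            )
            parts = np.diff(np.concatenate(([0], cuts, [defect_total])))
        else:
            parts = np.array([defect_total])
        region = n_bonds - right - left  # crystalline mid-region width
        free = region - defect_total  # = n_cryst, always >= 0
        gaps = rng.multinomial(free, np.full(n_patch + 1, 1.0 / (n_patch + 1)))
        pos = left
        for k, part in enumerate(parts):
            pos += int(gaps[k])
            cryst[pos : pos + int(part)] = False
            pos += int(part)
    return cryst


# ---------------------------------------------------------------------------
# chains and lattice geometry
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """One polymer slot on the lattice (or a free-floating chain).

    ``present`` tracks monomer occupancy (False = gap or solubilised),
    ``intact`` tracks glycosidic bonds (``intact[i]`` connects monomers
    ``i`` and ``i+1``), and ``crystalline`` labels bonds.  Lignin chains
    carry no digestible bonds.
    """

    cid: int
    kind: str  # 'cellulose' | 'hemicellulose' | 'lignin'
    layer: int  # 0 core, 1 inner shell, 2 outer shell, -1 free-floating
    coord: tuple[float, float]
    present: np.ndarray
    intact: np.ndarray
    crystalline: np.ndarray
    outward: list[int] = field(default_factory=list)
    inward: list[int] = field(default_factory=list)
    surface: bool = True
    is_outer: bool = True

    @property
    def lateral(self) -> list[int]:
        """All adjacent chains (each adjacency is outward on one side)."""
        return self.outward + self.inward

    @property
    def n_monomers(self) -> int:
        return len(self.present)

    @property
    def n_bonds(self) -> int:
        return len(self.intact)


def _axial_xy(q: int, r: int) -> tuple[float, float]:
    return (q + 0.5 * r, r * math.sqrt(3) / 2.0)


def _core_positions(n_chains: int) -> list[tuple[int, int]]:
    cols = _MODE_COLS[n_chains]
    rows = n_chains // cols
    return [(q - r // 2, r) for r in range(rows) for q in range(cols)]


def _ring(around: set[tuple[int, int]], exclude: set[tuple[int, int]]) -> list[tuple[int, int]]:
    ring = set()
    for (q, r) in around:
        for dq, dr in _AX_NEIGH:
            p = (q + dq, r + dr)
            if p not in exclude:
                ring.add(p)
    return sorted(ring)


def _place_segments(
    slot_lengths: list[int],
    total: int,
    rng: np.random.Generator,
    min_len: int = _SEG_MIN,
    max_len: int = _SEG_MAX,
) -> list[tuple[int, int, int]]:
    """Fill shell slots with random contiguous segments.

    Returns ``(slot, start, length)`` placements totalling ``total``
    monomers (or as many as fit).  Segment lengths are drawn uniformly in
    ``[min_len, max_len]`` and clipped to the chosen free interval and the
    remaining budget, never below the minimum insoluble fragment size.
    """
    free: list[list[tuple[int, int]]] = [[(0, L)] for L in slot_lengths]  # [start, end)
    placements: list[tuple[int, int, int]] = []
    remaining = int(total)
    while remaining >= _MIN_FRAGMENT:
        intervals = [
            (s, k, iv)
            for s, ivs in enumerate(free)
            for k, iv in enumerate(ivs)
            if iv[1] - iv[0] >= _MIN_FRAGMENT
        ]
        if not intervals:
            break
        lengths = np.array([iv[1] - iv[0] for _, _, iv in intervals], dtype=float)
        pick = int(rng.choice(len(intervals), p=lengths / lengths.sum()))
        slot, k, (a, b) = intervals[pick]
        seg = int(rng.integers(min_len, max_len + 1))
        seg = min(seg, b - a, remaining)
        seg = max(seg, _MIN_FRAGMENT)
        start = a + int(rng.integers(0, (b - a) - seg + 1))
        placements.append((slot, start, seg))
        remaining -= seg
        # split the free interval
        new = []
        if start - a >= 1:
            new.append((a, start))
        if b - (start + seg) >= 1:
            new.append((start + seg, b))
        free[slot][k : k + 1] = new
    return placements


# ---------------------------------------------------------------------------
# indexed set: O(1) add / discard / uniform sample
# ---------------------------------------------------------------------------


class IndexedSet:
    """Set with O(1) membership, insertion, removal and uniform sampling."""

    __slots__ = ("_items", "_pos")

    def __init__(self) -> None:
        self._items: list = []
        self._pos: dict = {}

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, key) -> bool:
        return key in self._pos

    def __iter__(self):
        return iter(self._items)

    def add(self, key) -> None:
        if key not in self._pos:
            self._pos[key] = len(self._items)
            self._items.append(key)

    def discard(self, key) -> None:
        pos = self._pos.pop(key, None)
        if pos is None:
            return
        last = self._items.pop()
        if pos < len(self._items):
            self._items[pos] = last
            self._pos[last] = pos

    def sample(self, rng: np.random.Generator):
        return self._items[int(rng.integers(len(self._items)))]

    def as_set(self) -> set:
        return set(self._items)


# ---------------------------------------------------------------------------
# substrate state
# ---------------------------------------------------------------------------


class SubstrateState:
    """Mutable simulation state of one substrate.

    Maintains, incrementally, the registries of enzyme-eligible targets:

    - ``eg_am`` / ``eg_cr``: (chain, bond) cellulose bonds eligible for
      endoglucanase cuts, split by bond state;
    - ``xyl_am`` / ``xyl_cr``: hemicellulose bonds eligible for
      hemicellulase cuts;
    - ``cbh_ends``: (chain, monomer) free cellulose fragment ends open for
      cellobiohydrolase attachment;
    - ``step_am`` / ``step_cr``: bound CBH ids, split by the crystallinity
      of the next bond they would cleave.

    The steric window ``h`` (monomers) couples enzyme size to the
    geometry: an enzyme reaches a shielded bond only through a vacancy of
    width ``2h`` on an outward neighbour chain, and bound CBHs exclude
    other enzymes within ``h`` monomers on the same chain.
    """

    def __init__(self, chains: list[Chain], config: SubstrateConfig, h: int, lignin_units: int):
        self.chains = chains
        self.config = config
        self.h = int(h)
        self.lignin_units = int(lignin_units)
        self.pools = {"glucose": 0, "cellobiose": 0, "xylose": 0}
        self.glucose_equivalents_total = int(
            sum(ch.present.sum() for ch in chains if ch.kind == "cellulose")
        )
        self.xylose_equivalents_total = int(
            sum(ch.present.sum() for ch in chains if ch.kind == "hemicellulose")
        )
        self.bound_cbh: dict[int, tuple[int, int, int]] = {}  # eid -> (chain, end monomer, dir)
        self._chain_cbh: dict[int, set[int]] = {}  # chain -> bound end positions
        self._next_eid = 0
        self.events_applied = 0
        self.eg_am = IndexedSet()
        self.eg_cr = IndexedSet()
        self.xyl_am = IndexedSet()
        self.xyl_cr = IndexedSet()
        self.cbh_ends = IndexedSet()
        self.step_am = IndexedSet()
        self.step_cr = IndexedSet()
        # at construction `intact` marks exactly the bonds that exist
        cryst = sum(
            int((ch.crystalline & ch.intact).sum())
            for ch in chains
            if ch.kind != "lignin"
        )
        total = sum(int(ch.intact.sum()) for ch in chains if ch.kind != "lignin")
        if total == 0:
            raise ConfigurationError("empty substrate: no carbohydrate bonds")
        #: crystalline fraction of the as-built carbohydrate bonds
        self.initial_crystallinity = cryst / total
        self.rebuild_open()
        self.rebuild_registries()

    # -- geometric accessibility -------------------------------------------
    #
    # Openness is solvent-connected reachability: a lattice site is open
    # if its chain is on the surface, or if some outward-neighbour chain
    # is vacant AND itself open over the full steric window, so that an
    # enzyme of the configured size can physically pass.  Both vacancy and
    # openness are monotone (sites never re-occupy, openings never close),
    # so open flags are set once and propagated inward.

    def _window_clear(self, o: int, lo: int, hi: int) -> bool:
        """All sites of chain ``o`` in [lo, hi) vacant and open."""
        oc = self.chains[o]
        lo = max(0, lo)
        hi = min(oc.n_monomers, hi)
        if hi <= lo:
            return True
        return not oc.present[lo:hi].any() and bool(self.open_[o][lo:hi].all())

    def bond_open(self, c: int, i: int) -> bool:
        """Is bond ``i`` of chain ``c`` reachable from the solvent?"""
        ch = self.chains[c]
        if ch.surface:
            return True
        return any(self._window_clear(o, i - self.h + 1, i + self.h + 1) for o in ch.outward)

    def _site_open_now(self, c: int, m: int) -> bool:
        ch = self.chains[c]
        if ch.surface:
            return True
        return any(self._window_clear(o, m - self.h, m + self.h + 1) for o in ch.outward)

    def rebuild_open(self) -> None:
        """From-scratch fixpoint of the open flags (test oracle)."""
        self.open_ = [
            np.full(ch.n_monomers, ch.surface, dtype=bool) for ch in self.chains
        ]
        changed = True
        while changed:
            changed = False
            for c, ch in enumerate(self.chains):
                if ch.surface:
                    continue
                for m in range(ch.n_monomers):
                    if not self.open_[c][m] and self._site_open_now(c, m):
                        self.open_[c][m] = True
                        changed = True

    def _surface_change(self, c: int, lo: int, hi: int) -> None:
        """Vacancy or openness changed on chain ``c`` over monomer span
        [lo, hi]: re-derive accessibility inward, propagating openings."""
        stack = [(c, lo, hi)]
        while stack:
            cc, a, b = stack.pop()
            for nb in self.chains[cc].inward:
                och = self.chains[nb]
                flip_lo = flip_hi = None
                for m in range(max(0, a - self.h), min(och.n_monomers, b + self.h + 1)):
                    if not self.open_[nb][m] and self._site_open_now(nb, m):
                        self.open_[nb][m] = True
                        flip_lo = m if flip_lo is None else flip_lo
                        flip_hi = m
                self._refresh_range(nb, a - self.h, b + self.h)
                if flip_lo is not None:
                    stack.append((nb, flip_lo, flip_hi))

    def _cbh_blocked(self, c: int, i: int) -> bool:
        """Steric exclusion: a bound CBH within ``h`` monomers of bond
        ``i``, on the same chain or a laterally adjacent one (the hard
        sphere covers a surface patch, not a single chain)."""
        for cc in (c, *self.chains[c].lateral):
            positions = self._chain_cbh.get(cc)
            if positions and any(p - self.h <= i <= p + self.h for p in positions):
                return True
        return False

    # -- eligibility predicates --------------------------------------------

    def _bond_eligible(self, c: int, i: int) -> bool:
        ch = self.chains[c]
        if not ch.intact[i]:
            return False
        if not self.bond_open(c, i):
            return False
        if ch.kind == "cellulose":
            # endoglucanase skips the two endmost bonds of each fragment
            if i < 2 or not (ch.intact[i - 1] and ch.intact[i - 2]):
                return False
            if i > ch.n_bonds - 3 or not (ch.intact[i + 1] and ch.intact[i + 2]):
                return False
            if self._cbh_blocked(c, i):
                return False
            return True
        if ch.kind == "hemicellulose":
            return True  # hemicellulases are non-specific
        return False

    def _end_info(self, c: int, m: int) -> int | None:
        """Direction (+1 left end, -1 right end) if monomer ``m`` heads a
        fragment of at least 3 monomers, else None."""
        ch = self.chains[c]
        if not (0 <= m < ch.n_monomers) or not ch.present[m]:
            return None
        left_open = m == 0 or not ch.intact[m - 1]
        right_open = m == ch.n_monomers - 1 or not ch.intact[m]
        if left_open and not right_open:
            if m + 1 < ch.n_bonds and ch.intact[m] and ch.intact[m + 1]:
                return 1
            return None
        if right_open and not left_open:
            if m - 2 >= 0 and ch.intact[m - 1] and ch.intact[m - 2]:
                return -1
            return None
        return None

    def _end_eligible(self, c: int, m: int) -> bool:
        ch = self.chains[c]
        if ch.kind != "cellulose":
            return False
        d = self._end_info(c, m)
        if d is None:
            return False
        access_bond = m if d == 1 else m - 1
        if not self.bond_open(c, access_bond):
            return False
        if self._cbh_blocked_end(c, m):
            return False
        return True

    def _cbh_blocked_end(self, c: int, m: int) -> bool:
        for cc in (c, *self.chains[c].lateral):
            positions = self._chain_cbh.get(cc)
            if positions and any(abs(p - m) <= self.h for p in positions):
                return True
        return False

    # -- registry maintenance ----------------------------------------------

    def refresh_bond(self, c: int, i: int) -> None:
        ch = self.chains[c]
        if not 0 <= i < ch.n_bonds or ch.kind == "lignin":
            return
        key = (c, i)
        if ch.kind == "cellulose":
            target, other = (
                (self.eg_cr, self.eg_am) if ch.crystalline[i] else (self.eg_am, self.eg_cr)
            )
        else:
            target, other = (
                (self.xyl_cr, self.xyl_am) if ch.crystalline[i] else (self.xyl_am, self.xyl_cr)
            )
        other.discard(key)
        if self._bond_eligible(c, i):
            target.add(key)
        else:
            target.discard(key)

    def refresh_end(self, c: int, m: int) -> None:
        ch = self.chains[c]
        if not 0 <= m < ch.n_monomers or ch.kind != "cellulose":
            return
        key = (c, m)
        occupied = m in self._chain_cbh.get(c, ())
        if not occupied and self._end_eligible(c, m):
            self.cbh_ends.add(key)
        else:
            self.cbh_ends.discard(key)

    def _refresh_range(self, c: int, lo: int, hi: int) -> None:
        """Refresh bonds and ends of chain ``c`` over monomer window [lo, hi]."""
        ch = self.chains[c]
        for i in range(max(0, lo), min(ch.n_bonds, hi + 1)):
            self.refresh_bond(c, i)
        for m in range(max(0, lo), min(ch.n_monomers, hi + 1)):
            self.refresh_end(c, m)


    def rebuild_registries(self) -> None:
        """From-scratch reconstruction of every target registry."""
        for s in (self.eg_am, self.eg_cr, self.xyl_am, self.xyl_cr, self.cbh_ends):
            s.__init__()
        for c, ch in enumerate(self.chains):
            if ch.kind == "lignin":
                continue
            for i in range(ch.n_bonds):
                self.refresh_bond(c, i)
            if ch.kind == "cellulose":
                for m in range(ch.n_monomers):
                    self.refresh_end(c, m)
        self.step_am.__init__()
        self.step_cr.__init__()
        for eid in self.bound_cbh:
            self._classify_cbh(eid)

    def registry_snapshot(self) -> dict[str, set]:
        return {
            name: getattr(self, name).as_set()
            for name in ("eg_am", "eg_cr", "xyl_am", "xyl_cr", "cbh_ends", "step_am", "step_cr")
        }

    # -- events --------------------------------------------------------------

    def _solubilise(self, c: int, a: int, b: int) -> None:
        """Move the fragment spanning monomers [a, b] (size <= 2) to the
        soluble pools and vacate its lattice sites."""
        ch = self.chains[c]
        size = b - a + 1
        ch.present[a : b + 1] = False
        for i in range(max(0, a - 1), min(ch.n_bonds, b + 1)):
            ch.intact[i] = False
        if ch.kind == "cellulose":
            if size == 1:
                self.pools["glucose"] += 1
            else:
                self.pools["cellobiose"] += 1
        else:  # hemicellulose: mono- and di-saccharides counted as xylose units
            self.pools["xylose"] += size
        self._refresh_range(c, a - 3, b + 3)
        self._surface_change(c, a, b)

    def _fragment_bounds(self, c: int, m: int) -> tuple[int, int]:
        """Monomer span [a, b] of the fragment containing monomer ``m``."""
        ch = self.chains[c]
        a = m
        while a > 0 and ch.intact[a - 1]:
            a -= 1
        b = m
        while b < ch.n_bonds and ch.intact[b]:
            b += 1
        return a, b

    def cleave(self, c: int, i: int) -> None:
        """Hydrolyse bond ``i`` of chain ``c`` (endoglucanase or
        hemicellulase cut), with fragment bookkeeping."""
        ch = self.chains[c]
        if not ch.intact[i]:
            raise RuntimeError(f"bond ({c}, {i}) is not intact")
        ch.intact[i] = False
        a, _ = self._fragment_bounds(c, i)
        _, b = self._fragment_bounds(c, i + 1)
        self._refresh_range(c, i - 3, i + 4)
        if i - a + 1 <= 2:  # left fragment monomers [a, i]
            self._solubilise(c, a, i)
        if b - (i + 1) + 1 <= 2:  # right fragment monomers [i+1, b]
            self._solubilise(c, i + 1, b)
        self.events_applied += 1

    # -- CBH handling ---------------------------------------------------------

    def _cbh_next_bond(self, eid: int) -> int:
        c, m, d = self.bound_cbh[eid]
        return m + 1 if d == 1 else m - 2

    def _classify_cbh(self, eid: int) -> None:
        c, m, d = self.bound_cbh[eid]
        nb = self._cbh_next_bond(eid)
        ch = self.chains[c]
        self.step_am.discard(eid)
        self.step_cr.discard(eid)
        if 0 <= nb < ch.n_bonds and ch.crystalline[nb]:
            self.step_cr.add(eid)
        else:
            self.step_am.add(eid)

    def cbh_attach(self, c: int, m: int) -> int:
        """Bind a cellobiohydrolase to the free end (c, m); returns its id."""
        if (c, m) not in self.cbh_ends:
            raise RuntimeError(f"end ({c}, {m}) is not attachable")
        eid = self._next_eid
        self._next_eid += 1
        d = self._end_info(c, m)
        self.bound_cbh[eid] = (c, m, d)
        self._chain_cbh.setdefault(c, set()).add(m)
        self._classify_cbh(eid)
        self._refresh_footprint(c, m - self.h - 1, m + self.h + 1)
        self.events_applied += 1
        return eid

    def _refresh_footprint(self, c: int, lo: int, hi: int) -> None:
        """Refresh a CBH steric footprint: own chain plus lateral ones."""
        self._refresh_range(c, lo, hi)
        for cc in self.chains[c].lateral:
            self._refresh_range(cc, lo, hi)

    def cbh_detach(self, eid: int) -> None:
        c, m, _ = self.bound_cbh.pop(eid)
        self._chain_cbh[c].discard(m)
        self.step_am.discard(eid)
        self.step_cr.discard(eid)
        self._refresh_footprint(c, m - self.h - 1, m + self.h + 1)

    def cbh_step(self, eid: int) -> None:
        """One processive cleavage: release a cellobiose from the attached
        end, or detach if the path ahead is shielded or blocked."""
        c, m, d = self.bound_cbh[eid]
        ch = self.chains[c]
        cut = self._cbh_next_bond(eid)
        new_end = m + 2 * d
        blocked = any(
            abs(p - new_end) <= self.h for p in self._chain_cbh.get(c, ()) if p != m
        )
        if not self.bond_open(c, cut) or blocked:
            self.cbh_detach(eid)
            self.events_applied += 1
            return
        removed = (m, m + 1) if d == 1 else (m - 1, m)
        inner_bond = m if d == 1 else m - 1  # bond internal to the released dimer
        ch.intact[cut] = False
        ch.intact[inner_bond] = False
        ch.present[removed[0]] = False
        ch.present[removed[1]] = False
        self.pools["cellobiose"] += 1
        # move the enzyme along
        self._chain_cbh[c].discard(m)
        a, b = self._fragment_bounds(c, new_end)
        if b - a + 1 < _MIN_FRAGMENT:
            self.bound_cbh.pop(eid)
            self.step_am.discard(eid)
            self.step_cr.discard(eid)
            self._solubilise(c, a, b)
        else:
            self.bound_cbh[eid] = (c, new_end, d)
            self._chain_cbh[c].add(new_end)
            self._classify_cbh(eid)
        lo, hi = min(removed[0], new_end), max(removed[1], new_end)
        self._refresh_footprint(c, lo - self.h - 3, hi + self.h + 3)
        self._surface_change(c, removed[0], removed[1])
        self.events_applied += 1

    def bgl_split(self) -> None:
        """beta-glucosidase: one cellobiose -> two glucose."""
        if self.pools["cellobiose"] < 1:
            raise RuntimeError("cellobiose pool empty")
        self.pools["cellobiose"] -= 1
        self.pools["glucose"] += 2
        self.events_applied += 1

    # -- observables ----------------------------------------------------------

    def glucose_balance(self) -> int:
        """Lattice glucose equivalents + 2*cellobiose + glucose (conserved)."""
        lattice = sum(int(ch.present.sum()) for ch in self.chains if ch.kind == "cellulose")
        return lattice + 2 * self.pools["cellobiose"] + self.pools["glucose"]

    def conversion_cellulose(self) -> float:
        """% of initial cellulose glucose equivalents solubilised."""
        if self.glucose_equivalents_total == 0:
            return 0.0
        sol = self.pools["glucose"] + 2 * self.pools["cellobiose"]
        return 100.0 * sol / self.glucose_equivalents_total

    def exposed_bonds(self) -> set[tuple[int, int]]:
        """All intact, solvent-reachable carbohydrate bonds."""
        out = set()
        for c, ch in enumerate(self.chains):
            if ch.kind == "lignin":
                continue
            for i in range(ch.n_bonds):
                if ch.intact[i] and self.bond_open(c, i):
                    out.add((c, i))
        return out

    def exposure_fraction(self) -> float:
        intact = sum(
            int(ch.intact.sum()) for ch in self.chains if ch.kind != "lignin"
        )
        if intact == 0:
            return 0.0
        return len(self.exposed_bonds()) / intact

    def free_ends(self) -> set[tuple[int, int]]:
        return self.cbh_ends.as_set()

    def to_json(self) -> str:
        """Snapshot (chains, bond states, exposure) for debugging/tests."""
        payload = {
            "config": {
                "mode_code": self.config.mode_code,
                "length_fibril": self.config.length_fibril,
                "free_floating": self.config.free_floating,
            },
            "h": self.h,
            "lignin_units": self.lignin_units,
            "pools": self.pools,
            "chains": [
                {
                    "cid": ch.cid,
                    "kind": ch.kind,
                    "layer": ch.layer,
                    "present": ch.present.astype(int).tolist(),
                    "intact": ch.intact.astype(int).tolist(),
                    "crystalline": ch.crystalline.astype(int).tolist(),
                }
                for ch in self.chains
            ],
            "exposed_bonds": sorted(self.exposed_bonds()),
        }
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _monomer_budgets(config: SubstrateConfig) -> tuple[int, int, int]:
    comp = config.composition
    n_mono = config.length_fibril + 1
    c_total = config.n_chains * n_mono
    hemi = int(round(c_total * comp.pct_hemicellulose / comp.pct_cellulose))
    lign = int(round(c_total * comp.pct_lignin / comp.pct_cellulose))
    return c_total, hemi, lign


def build_microfibril(
    config: SubstrateConfig,
    rng: np.random.Generator,
    steric_window: int = 3,
) -> SubstrateState:
    """Assemble the shielded microfibril substrate.

    The cellulose core sits on a triangular lattice cross-section; the
    inner shell ring holds hemicellulose segments, the outer ring lignin
    monolignol runs, both placed at random until the composition-derived
    monomer budgets are met.  Unfilled shell positions are gaps.  Only
    bonds reachable from the solvent (surface chains, or shielded chains
    under a sufficiently wide gap) start out exposed.
    """
    if config.free_floating:
        raise ConfigurationError("config.free_floating is set; use build_free_substrate")
    n_mono = config.length_fibril + 1
    core = _core_positions(config.n_chains)
    core_set = set(core)
    inner = _ring(core_set, core_set)
    outer = _ring(core_set | set(inner), core_set | set(inner))

    positions = [(p, 0) for p in core] + [(p, 1) for p in inner] + [(p, 2) for p in outer]
    xy = {p: _axial_xy(*p) for p, _ in positions}
    cx = np.mean([xy[p][0] for p in core])
    cy = np.mean([xy[p][1] for p in core])
    dist = {p: math.hypot(xy[p][0] - cx, xy[p][1] - cy) for p, _ in positions}
    layer_of = {p: l for p, l in positions}

    chains: list[Chain] = []
    index_of: dict[tuple[int, int], int] = {}

    _, hemi_budget, lignin_budget = _monomer_budgets(config)

    # core cellulose chains
    for p in core:
        cid = len(chains)
        index_of[p] = cid
        neigh_layers = [layer_of.get((p[0] + dq, p[1] + dr)) for dq, dr in _AX_NEIGH]
        is_outer = any(l is not None and l > 0 for l in neigh_layers)
        chains.append(
            Chain(
                cid=cid,
                kind="cellulose",
                layer=0,
                coord=xy[p],
                present=np.ones(n_mono, dtype=bool),
                intact=np.ones(config.length_fibril, dtype=bool),
                crystalline=assign_crystallinity(
                    config.length_fibril,
                    config.CF_cellu,
                    config.mu_defect,
                    config.N_defect,
                    is_outer,
                    rng,
                ),
                surface=False,
                is_outer=is_outer,
            )
        )

    # shell slots start vacant; segments fill them below
    for ring_positions, layer, kind in ((inner, 1, "hemicellulose"), (outer, 2, "lignin")):
        for p in ring_positions:
            cid = len(chains)
            index_of[p] = cid
            chains.append(
                Chain(
                    cid=cid,
                    kind=kind,
                    layer=layer,
                    coord=xy[p],
                    present=np.zeros(n_mono, dtype=bool),
                    intact=np.zeros(max(n_mono - 1, 0), dtype=bool),
                    crystalline=np.zeros(max(n_mono - 1, 0), dtype=bool),
                    surface=(layer == 2),
                    is_outer=True,
                )
            )

    inner_ids = [index_of[p] for p in inner]
    outer_ids = [index_of[p] for p in outer]

    # hemicellulose segments in the inner shell
    placements = _place_segments([n_mono] * len(inner_ids), hemi_budget, rng)
    for slot, start, seg in placements:
        ch = chains[inner_ids[slot]]
        ch.present[start : start + seg] = True
        ch.intact[start : start + seg - 1] = True
        ch.crystalline[start : start + seg - 1] = assign_crystallinity(
            seg - 1, config.CF_hemi, config.mu_defect, config.N_defect, True, rng
        )

    # lignin monolignol runs in the outer shell
    placements = _place_segments([n_mono] * len(outer_ids), lignin_budget, rng)
    placed_lignin = 0
    for slot, start, seg in placements:
        chains[outer_ids[slot]].present[start : start + seg] = True
        placed_lignin += seg
    if placed_lignin < lignin_budget - _SEG_MAX:
        warnings.warn(
            f"outer shell saturated: placed {placed_lignin}/{lignin_budget} monolignols",
            stacklevel=2,
        )

    # adjacency: outward = higher layer, or same layer strictly farther from axis
    for p, _l in positions:
        cid = index_of[p]
        ch = chains[cid]
        for dq, dr in _AX_NEIGH:
            q = (p[0] + dq, p[1] + dr)
            if q not in index_of:
                continue
            lo, lq = layer_of[p], layer_of[q]
            outward = lq > lo or (
                lq == lo
                and (
                    dist[q] > dist[p] + 1e-9
                    or (abs(dist[q] - dist[p]) <= 1e-9 and xy[q] > xy[p])
                )
            )
            if outward:
                ch.outward.append(index_of[q])
                chains[index_of[q]].inward.append(cid)

    state = SubstrateState(chains, config, steric_window, lignin_units=placed_lignin)
    return state


def build_free_substrate(
    config: SubstrateConfig,
    rng: np.random.Generator,
    steric_window: int = 3,
) -> SubstrateState:
    """Free-floating polymers: every bond solvent-exposed, lignin dissolved.

    The polymer inventory (chain counts, lengths, crystallinity) matches
    the microfibril mode for the same composition, but there is no lattice
    shielding and lignin enters only the enzyme-adsorption bookkeeping.
    """
    if not config.free_floating:
        raise ConfigurationError("config.free_floating is not set; use build_microfibril")
    n_mono = config.length_fibril + 1
    _, hemi_budget, lignin_budget = _monomer_budgets(config)
    chains: list[Chain] = []
    for _ in range(config.n_chains):
        cid = len(chains)
        chains.append(
            Chain(
                cid=cid,
                kind="cellulose",
                layer=-1,
                coord=(0.0, 0.0),
                present=np.ones(n_mono, dtype=bool),
                intact=np.ones(config.length_fibril, dtype=bool),
                crystalline=assign_crystallinity(
                    config.length_fibril,
                    config.CF_cellu,
                    config.mu_defect,
                    config.N_defect,
                    True,
                    rng,
                ),
                surface=True,
                is_outer=True,
            )
        )
    remaining = hemi_budget
    while remaining >= _MIN_FRAGMENT:
        seg = int(rng.integers(_SEG_MIN, _SEG_MAX + 1))
        seg = max(_MIN_FRAGMENT, min(seg, remaining))
        cid = len(chains)
        chains.append(
            Chain(
                cid=cid,
                kind="hemicellulose",
                layer=-1,
                coord=(0.0, 0.0),
                present=np.ones(seg, dtype=bool),
                intact=np.ones(seg - 1, dtype=bool),
                crystalline=assign_crystallinity(
                    seg - 1, config.CF_hemi, config.mu_defect, config.N_defect, True, rng
                ),
                surface=True,
                is_outer=True,
            )
        )
        remaining -= seg
    return SubstrateState(chains, config, steric_window, lignin_units=lignin_budget)


def build_substrate(
    config: SubstrateConfig,
    rng: np.random.Generator,
    steric_window: int = 3,
) -> SubstrateState:
    """Dispatch on ``config.free_floating``."""
    if config.free_floating:
        return build_free_substrate(config, rng, steric_window)
    return build_microfibril(config, rng, steric_window)


def average_crystallinity(obj: SubstrateState | SubstrateConfig) -> float:
    """Substrate-average crystallinity over carbohydrate bonds.

    For a built state, the exact crystalline-bond fraction over cellulose
    plus hemicellulose bonds (lignin excluded).  For a config, the
    monomer-budget-weighted analytic average of ``CF_cellu`` / ``CF_hemi``.
    """
    if isinstance(obj, SubstrateState):
        return obj.initial_crystallinity
    config = obj
    c_total, hemi, _ = _monomer_budgets(config)
    if c_total + hemi == 0:
        raise ConfigurationError("empty substrate")
    return (config.CF_cellu * c_total + config.CF_hemi * hemi) / (c_total + hemi)
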