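"""Opening energy of anchored mRNA regions over the Boltzmann ensemble.

The opening energy of a region i..j is the pseudo-energy required to unpair
it, ``-RT ln(Z_unpaired / Z)``, where Z is the total partition function over
secondary structures and Z_unpaired restricts the ensemble to structures in
which every base of the region is unpaired.  Low opening energy means high
accessibility.  Two interchangeable engines are provided:

* ``production`` — ViennaRNA's sliding-window partition function
  (the RNAplfold algorithm, nearest-neighbour Turner energies), computed over
  windows of width W covering the region plus flanks.
* ``toy`` — an exact McCaskill-style partition function over the full
  sequence under a deliberately non-physical model (a constant energy per
  Watson-Crick/GU pair, minimum hairpin loop of 3).  It exists to make the
  ensemble bookkeeping testable against brute-force enumeration.

Both satisfy the same adapter contract: the probability that the stretch of
exactly the region's length ending at the region's end is unpaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core_seq import (
    CodingConstruct,
    RegionSpec,
    endpos_len_to_region,
    region_to_offsets,
)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FoldConfig",
    "PartitionResult",
    "OpeningEnergyProfile",
    "EngineUnavailableError",
    "thermal_energy",
    "unpaired_probability",
    "opening_energy",
    "mfe_region",
    "scan_profile",
    "toy_partition",
    "toy_mfe",
    "toy_partition_oracle",
    "count_structures",
    "get_engine",
]

#: gas constant in kcal/(mol*K)
GAS_CONSTANT_KCAL = 0.0019872


def thermal_energy(temperature_c: float = 37.0) -> float:
    """RT in kcal/mol at a Celsius temperature (0.6163 at 37 C)."""
    return GAS_CONSTANT_KCAL * (temperature_c + 273.15)


class EngineUnavailableError(RuntimeError):
    """The requested folding engine cannot be constructed.

    An engine adapter must expose ``stretch_unpaired_probability(seq, lo, hi)``
    returning the ensemble probability that positions [lo, hi) are all
    unpaired, plus ``name`` and ``version`` attributes.
    """


@dataclass(frozen=True)
class FoldConfig:
    """Folding-engine settings.

    ``window_size`` (W) and ``max_stretch`` (u) default to 210 nt, the values
    used for sliding-window accessibility of initiation regions; regions up to
    ``max_stretch`` long can be scored.  The toy engine ignores W and folds
    the full sequence; its per-pair energy and minimum hairpin loop are
    configurable and documented as non-physical.
    """

    window_size: int = 210
    max_stretch: int = 210
    temperature: float = 37.0
    engine: str = "production"
    pair_energy: float = -1.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.max_stretch <= self.window_size):
            raise ValueError("need 1 <= max_stretch <= window_size")

    @property
    def rt(self) -> float:
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class PartitionResult:
    """Total and region-constrained partition functions."""

    z: float
    z_unpaired: float

    def __post_init__(self) -> None:
        if not (0.0 < self.z_unpaired <= self.z * (1 + 1e-12)):
            raise ValueError(
                f"need 0 < Z_unpaired <= Z, got {self.z_unpaired} vs {self.z}"
            )

    @property
    def p_unpaired(self) -> float:
        return min(self.z_unpaired / self.z, 1.0)


# --- toy engine: exact partition function, simple pair model -----------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _pair_matrix(seq: str, min_loop: int, blocked: np.ndarray | None = None) -> np.ndarray:
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (seq[i], seq[j]) in _PAIRS:
                ok[i, j] = True
    if blocked is not None:
        ok[blocked, :] = False
        ok[:, blocked] = False
    return ok


def _toy_z(seq: str, boltz: float, min_loop: int,
           blocked: np.ndarray | None = None) -> float:
    """Partition function over nested structures, O(n^3).

    ``Z[i, j]`` covers the inclusive subsequence i..j; empty intervals have
    Z = 1 (the open chain contributes a Boltzmann factor of 1).
    """
    n = len(seq)
    ok = _pair_matrix(seq, min_loop, blocked)
    # padded so that Z[k+1, j] with k = j reads 1
    z = np.ones((n + 2, n + 2))
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            ks = np.nonzero(ok[i, i : j + 1])[0] + i
            total = z[i + 1, j]
            if ks.size:
                total += boltz * float(np.dot(z[i + 1, ks - 1], z[ks + 1, j]))
            z[i, j] = total
    out = float(z[0, n - 1]) if n else 1.0
    if not math.isfinite(out):
        raise OverflowError(
            f"toy partition function overflowed for a {n} nt sequence; "
            "use shorter sequences or a weaker pair energy"
        )
    return out


def toy_partition(seq: str, interval: tuple[int, int] | None = None,
                  config: FoldConfig | None = None) -> PartitionResult:
    """Exact toy-model partition function, optionally region-constrained.

    ``interval`` is a zero-based half-open stretch required to be unpaired in
    the constrained ensemble (pairs may still arch over it).
    """
    config = config or FoldConfig(engine="toy")
    boltz = math.exp(-config.pair_energy / config.rt)
    z = _toy_z(seq, boltz, config.min_loop)
    if interval is None:
        return PartitionResult(z=z, z_unpaired=z)
    lo, hi = interval
    if not (0 <= lo < hi <= len(seq)):
        raise IndexError(f"interval [{lo}, {hi}) outside sequence of {len(seq)} nt")
    blocked = np.zeros(len(seq), dtype=bool)
    blocked[lo:hi] = True
    zu = _toy_z(seq, boltz, config.min_loop, blocked)
    return PartitionResult(z=z, z_unpaired=zu)


def toy_mfe(seq: str, config: FoldConfig | None = None) -> float:
    """Minimum free energy under the toy pair model (maximum pairing DP)."""
    config = config or FoldConfig(engine="toy")
    n = len(seq)
    ok = _pair_matrix(seq, config.min_loop)
    best = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(config.min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            cand = best[i + 1, j]
            ks = np.nonzero(ok[i, i : j + 1])[0] + i
            if ks.size:
                cand = max(cand, int((1 + best[i + 1, ks - 1] + best[ks + 1, j]).max()))
            best[i, j] = cand
    return config.pair_energy * int(best[0, n - 1]) if n else 0.0


# --- brute-force enumeration oracle ------------------------------------------

_ORACLE_LIMIT = 30


def _enumerate_structures(seq: str, min_loop: int) -> list[tuple[tuple[int, int], ...]]:
    """Every nested structure as a sorted tuple of 0-based pair indices."""

    pairs_ok = _pair_matrix(seq, min_loop)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i + 1 <= min_loop:  # too short to hold any pair
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pairs_ok[i, k]:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    if not seq:
        return [()]
    return [tuple(sorted(s)) for s in rec(0, len(seq) - 1)]


def count_structures(seq: str, min_loop: int = 3) -> int:
    """Independent structure count via an end-anchored recurrence.

    Counts nested structures by conditioning on the *last* position (unpaired,
    or paired with some k) — a different decomposition from the enumerator's
    first-position recursion, used as a cross-check.
    """
    n = len(seq)
    ok = _pair_matrix(seq, min_loop)

    @lru_cache(maxsize=None)
    def cnt(i: int, j: int) -> int:
        if j - i + 1 <= min_loop:
            return 1
        total = cnt(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if ok[k, j]:
                left = cnt(i, k - 1) if k > i else 1
                total += left * cnt(k + 1, j - 1)
        return total

    return cnt(0, n - 1) if n else 1


def toy_partition_oracle(seq: str, interval: tuple[int, int] | None = None,
                         config: FoldConfig | None = None,
                         return_structures: bool = False):
    """Brute-force partition function by structure enumeration (<= 30 nt).

    Enumerates every nested structure with Watson-Crick + GU pairs and
    minimum hairpin loop per the toy model, sums Boltzmann factors for Z, and
    restricts to structures leaving ``interval`` unpaired for Z_unpaired.
    """
    config = config or FoldConfig(engine="toy")
    if len(seq) > _ORACLE_LIMIT:
        raise ValueError(
            f"enumeration oracle is limited to {_ORACLE_LIMIT} nt "
            f"(got {len(seq)} nt)"
        )
    structures = _enumerate_structures(seq, config.min_loop)
    n_check = count_structures(seq, config.min_loop)
    if len(structures) != n_check:
        raise AssertionError(
            f"structure enumeration ({len(structures)}) disagrees with "
            f"recursion count ({n_check})"
        )
    boltz = math.exp(-config.pair_energy / config.rt)
    z = 0.0
    zu = 0.0
    lo, hi = interval if interval is not None else (0, 0)
    for struct in structures:
        w = boltz ** len(struct)
        z += w
        if interval is None or all(not (lo <= a < hi or lo <= b < hi) for a, b in struct):
            zu += w
    result = PartitionResult(z=z, z_unpaired=zu if interval is not None else z)
    if return_structures:
        return result, structures
    return result


# --- engine adapters ---------------------------------------------------------

class ToyEngine:
    """Full-sequence exact engine under the toy pair model."""

    name = "toy"
    version = "exact-dp"

    def __init__(self, config: FoldConfig):
        self.config = config

    def stretch_unpaired_probability(self, seq: str, lo: int, hi: int) -> float:
        return toy_partition(seq, (lo, hi), self.config).p_unpaired

    def mfe(self, seq: str) -> float:
        return toy_mfe(seq, self.config)


class ViennaEngine:
    """Sliding-window partition-function engine (ViennaRNA bindings).

    Implements the RNAplfold computation: windows of width W slide over the
    sequence, and the reported probability that a stretch is unpaired is
    averaged over all windows covering it, so flanking context up to W nt
    beyond the region contributes.
    """

    name = "viennarna"

    def __init__(self, config: FoldConfig):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - present in CI image
            raise EngineUnavailableError(
                "ViennaRNA Python bindings are required for the production "
                "engine; install the 'viennarna' package or use "
                "FoldConfig(engine='toy'). Adapter contract: "
                "stretch_unpaired_probability(seq, lo, hi) -> probability."
            ) from exc
        self._rna = RNA
        self.config = config
        self.version = RNA.__version__

    def _with_temperature(self):
        rna = self._rna
        old = rna.cvar.temperature
        rna.cvar.temperature = self.config.temperature
        return old

    def stretch_unpaired_probability(self, seq: str, lo: int, hi: int) -> float:
        rna = self._rna
        u = hi - lo
        w = min(self.config.window_size, len(seq))
        old = self._with_temperature()
        try:
            up = rna.pfl_fold_up(seq, u, w, w)
        finally:
            rna.cvar.temperature = old
        # up[i][u]: probability that the u-stretch ending at 1-based i is unpaired
        p = float(up[hi][u])
        return min(max(p, 0.0), 1.0)

    def mfe(self, seq: str) -> float:
        rna = self._rna
        old = self._with_temperature()
        try:
            _, energy = rna.fold(seq)
        finally:
            rna.cvar.temperature = old
        return float(energy)


def get_engine(config: FoldConfig):
    if config.engine == "toy":
        return ToyEngine(config)
    if config.engine == "production":
        return ViennaEngine(config)
    raise ValueError(f"unknown engine {config.engine!r}")


# --- public operations -------------------------------------------------------

def unpaired_probability(seq: str, interval: tuple[int, int],
                         config: FoldConfig | None = None,
                         engine=None) -> float:
    """Probability that the nucleotides of ``interval`` are all unpaired."""
    config = config or FoldConfig()
    lo, hi = interval
    if not (0 <= lo < hi <= len(seq)):
        raise IndexError(f"interval [{lo}, {hi}) outside sequence of {len(seq)} nt")
    if hi - lo > config.max_stretch:
        raise ValueError(
            f"stretch of {hi - lo} nt exceeds max_stretch {config.max_stretch}"
        )
    engine = engine or get_engine(config)
    p = engine.stretch_unpaired_probability(seq, lo, hi)
    if not (0.0 < p <= 1.0):
        raise ArithmeticError(f"engine returned invalid probability {p}")
    return p


def opening_energy(construct: CodingConstruct, region: RegionSpec,
                   config: FoldConfig | None = None, engine=None) -> float:
    """Opening energy -RT ln p(region unpaired), in kcal/mol (>= 0)."""
    config = config or FoldConfig()
    interval = region_to_offsets(region, construct)
    p = unpaired_probability(construct.sequence, interval, config, engine=engine)
    return max(0.0, -config.rt * math.log(p))


def mfe_region(construct: CodingConstruct, region: RegionSpec,
               config: FoldConfig | None = None, engine=None) -> float:
    """MFE (kcal/mol) of the single most stable structure of the excised region."""
    config = config or FoldConfig()
    lo, hi = region_to_offsets(region, construct)
    engine = engine or get_engine(config)
    return engine.mfe(construct.sequence[lo:hi])


@dataclass
class OpeningEnergyProfile:
    """Grid of opening energies indexed by (end position i, length l).

    Cells whose region does not fit inside the construct are NaN (undefined),
    never zero.
    """

    i_values: list[int]
    l_values: list[int]
    energies: np.ndarray  # shape (len(l_values), len(i_values)), NaN = undefined
    construct_id: str = ""
    engine_name: str = ""
    engine_version: str = ""

    def energy(self, i: int, l: int) -> float:
        return float(
            self.energies[self.l_values.index(l), self.i_values.index(i)]
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for li, l in enumerate(self.l_values):
            for ii, i in enumerate(self.i_values):
                val = self.energies[li, ii]
                if np.isnan(val):
                    continue
                region = endpos_len_to_region(i, l)
                rows.append(
                    {"i": i, "l": l, "region_start": region.start,
                     "region_end": region.end, "opening_energy": float(val)}
                )
        return pd.DataFrame(rows, columns=["i", "l", "region_start",
                                           "region_end", "opening_energy"])


def scan_profile(construct: CodingConstruct, lengths, end_positions,
                 config: FoldConfig | None = None, engine=None) -> OpeningEnergyProfile:
    """Opening energies over an (end position, length) grid.

    Each defined cell equals ``opening_energy`` of the corresponding region;
    grid cells whose region would need more flank than the construct provides
    are left undefined.
    """
    config = config or FoldConfig()
    lengths = sorted(set(int(l) for l in lengths))
    end_positions = sorted(set(int(i) for i in end_positions), key=lambda c: (c > 0, c))
    if not lengths or not end_positions:
        raise ValueError("empty scan grid")
    if any(i == 0 for i in end_positions):
        raise ValueError("anchored coordinates have no position 0")
    engine = engine or get_engine(config)
    grid = np.full((len(lengths), len(end_positions)), np.nan)
    any_defined = False
    for li, l in enumerate(lengths):
        for ii, i in enumerate(end_positions):
            region = endpos_len_to_region(i, l)
            try:
                grid[li, ii] = opening_energy(construct, region, config, engine=engine)
                any_defined = True
            except (IndexError, ValueError):
                continue
    if not any_defined:
        raise ValueError("no (i, l) grid cell fits inside the construct")
    return OpeningEnergyProfile(
        i_values=end_positions,
        l_values=lengths,
        energies=grid,
        construct_id=construct.id,
        engine_name=getattr(engine, "name", "?"),
        engine_version=str(getattr(engine, "version", "?")),
    )
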