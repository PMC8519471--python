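"""Simulated-annealing synonymous-codon optimization of opening energy.

Accessibility of the initiation region is optimized by substituting
synonymous codons among the first N codons of the CDS (N = 9 by default;
the start codon is never touched, nor is the stop codon).  Moves follow a
Metropolis-Hastings chain under an exponentially cooling temperature: the
first move at T = T0 substitutes every replaceable codon, late moves touch a
single codon.  Multiple independent chains are run and their best sequences
deduplicated, motif-filtered and ranked.  An exhaustive enumeration oracle
is provided for small search spaces.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_seq import (
    STOP_CODONS,
    CodingConstruct,
    RegionSpec,
    synonymous_codons,
)

__all__ = [
    "DEFAULT_FORBIDDEN_MOTIFS",
    "AnnealConfig",
    "Solution",
    "OptimizationResult",
    "replaceable_positions",
    "count_search_space",
    "propose",
    "metropolis_accept",
    "motif_filter",
    "anneal",
    "exhaustive_optimum",
]

#: restriction-modification sites avoided by default (checked on both strands)
DEFAULT_FORBIDDEN_MOTIFS: dict[str, str] = {
    "AarI": "CACCTGC",
    "BsaI": "GGTCTC",
    "BsmBI": "CGTCTC",
}

FULL = None  # sentinel: allow substitutions over the full CDS


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule, constraints and objective.

    ``n_codons`` counts substitutable codons downstream of the fixed start
    codon (codon indices 2..n_codons+1); ``None`` means the full CDS minus
    start and stop.  ``objective`` is "minimize" (maximize accessibility),
    "maximize", or "target" with ``target_energy`` set, which ranks
    candidates by |energy - target|.  Cooling is T(k) = t0 * cooling^k.
    """

    n_codons: int | None = 9
    chains: int = 10
    max_iterations: int = 1000
    t0: float = 1.0
    cooling: float = 0.99
    patience: int = 200
    seed: int | None = None
    objective: str = "minimize"
    target_energy: float | None = None
    forbidden_motifs: tuple[str, ...] = tuple(DEFAULT_FORBIDDEN_MOTIFS.values())
    scoring_region: RegionSpec = field(default_factory=lambda: RegionSpec(-24, 24))

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need chains >= 1")
        if self.t0 <= 0:
            raise ValueError("need T0 > 0")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling constant must be in (0, 1)")
        if self.objective not in ("minimize", "maximize", "target"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "target" and self.target_energy is None:
            raise ValueError("objective 'target' needs target_energy")

    def badness(self, energy: float) -> float:
        """Objective as a quantity to minimize."""
        if self.objective == "minimize":
            return energy
        if self.objective == "maximize":
            return -energy
        return abs(energy - self.target_energy)


def replaceable_positions(construct: CodingConstruct,
                          n_codons: int | None = 9) -> list[int]:
    """1-based codon indices eligible for synonymous substitution.

    The start codon (index 1) is never replaceable and neither is a terminal
    stop codon.  ``n_codons = k`` yields indices 2..k+1 clipped to the CDS
    (with a warning when clipping occurs); ``None`` means the full CDS.
    """
    construct.assert_canonical()
    codons = construct.codons()
    last = len(codons)
    if codons[-1] in STOP_CODONS:
        last -= 1
    if n_codons is None:
        return list(range(2, last + 1))
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1 or None")
    hi = n_codons + 1
    if hi > last:
        warnings.warn(
            f"{construct.id}: only {max(last - 1, 0)} substitutable codons "
            f"available; clipping n_codons={n_codons}", stacklevel=2,
        )
        hi = last
    return list(range(2, hi + 1))


def _variable_positions(construct: CodingConstruct, positions: list[int]) -> list[int]:
    """Positions whose codon has at least one alternative synonym."""
    codons = construct.codons()
    return [p for p in positions if len(synonymous_codons(codons[p - 1])) > 1]


def count_search_space(construct: CodingConstruct,
                       n_codons: int | None = 9) -> int:
    """Number of synonymous variants over the replaceable codons, input excluded."""
    codons = construct.codons()
    total = 1
    for p in replaceable_positions(construct, n_codons):
        total *= len(synonymous_codons(codons[p - 1]))
    return total - 1


def motif_filter(seq: str, motifs) -> tuple[bool, list[tuple[str, int, str]]]:
    """Scan for forbidden motifs on both strands.

    Returns (passes, hits); each hit is (motif, zero-based offset, strand)
    where the offset for the reverse strand is the position of the motif's
    reverse complement on the forward sequence.
    """
    comp = str.maketrans("ACGT", "TGCA")
    hits: list[tuple[str, int, str]] = []
    for motif in motifs:
        for target, strand in ((motif, "+"), (motif.translate(comp)[::-1], "-")):
            start = seq.find(target)
            while start != -1:
                hits.append((motif, start, strand))
                start = seq.find(target, start + 1)
    return (not hits), hits


def propose(codons: list[str], temperature: float, t0: float,
            replaceable: list[int], rng: np.random.Generator) -> list[str]:
    """One annealing move: substitute m codons, m shrinking with temperature.

    m = max(1, round((T/T0) * |replaceable|)): the first move is drastic
    (every replaceable codon substituted), late moves touch a single codon.
    Each chosen codon moves to a uniformly chosen *different* synonym, so the
    encoded protein is always conserved.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    replaceable = [p for p in replaceable
                   if len(synonymous_codons(codons[p - 1])) > 1]
    if not replaceable:
        raise ValueError("no replaceable codon has an alternative synonym")
    m = max(1, round(min(temperature / t0, 1.0) * len(replaceable)))
    m = min(m, len(replaceable))
    chosen = rng.choice(len(replaceable), size=m, replace=False)
    out = list(codons)
    for idx in chosen:
        pos = replaceable[idx]
        current = out[pos - 1]
        alts = sorted(synonymous_codons(current) - {current})
        out[pos - 1] = alts[rng.integers(len(alts))]
    return out


def metropolis_accept(e_new: float, e_old: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis rule for a minimization objective.

    Improving moves are always accepted; a worsening move of size dE is
    accepted with probability exp(-dE / T).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    delta = e_new - e_old
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / temperature))


@dataclass(frozen=True)
class Solution:
    cds: str
    energy: float
    n_substitutions: int
    codons_changed: tuple[int, ...]
    chain: int


@dataclass
class OptimizationResult:
    construct: CodingConstruct
    input_energy: float
    solutions: list[Solution]
    trajectories: list[list[tuple[int, float, float, bool]]]
    config: AnnealConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> Solution:
        return self.solutions[0]

    def solutions_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rank": r + 1,
                    "cds": s.cds,
                    "opening_energy": s.energy,
                    "n_substitutions": s.n_substitutions,
                    "codons_changed": ",".join(map(str, s.codons_changed)),
                    "chain": s.chain,
                }
                for r, s in enumerate(self.solutions)
            ]
        )

    def trajectory_frame(self):
        import pandas as pd

        rows = []
        for chain, traj in enumerate(self.trajectories):
            for iteration, temperature, energy, accepted in traj:
                rows.append(
                    {"chain": chain, "iteration": iteration,
                     "temperature": temperature, "energy": energy,
                     "accepted": accepted}
                )
        return pd.DataFrame(rows, columns=["chain", "iteration", "temperature",
                                           "energy", "accepted"])


def _diff_stats(original: list[str], candidate: list[str]) -> tuple[int, tuple[int, ...]]:
    nt = sum(a != b for ca, cb in zip(original, candidate) for a, b in zip(ca, cb))
    codons = tuple(i + 1 for i, (ca, cb) in enumerate(zip(original, candidate)) if ca != cb)
    return nt, codons


def anneal(construct: CodingConstruct, config: AnnealConfig, energy_fn) -> OptimizationResult:
    """Run ``config.chains`` seeded annealing chains and rank the solutions.

    ``energy_fn(cds) -> kcal/mol`` evaluates the opening energy of the
    scoring region for a candidate CDS spliced into the construct.  Per
    chain the best-so-far sequence is retained; best sequences are
    deduplicated across chains, motif-filtered and ranked by the objective.
    Deterministic for a fixed ``config.seed``.
    """
    construct.assert_canonical()
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        positions = replaceable_positions(construct, config.n_codons)
        notes.extend(str(w.message) for w in caught)
    replaceable = _variable_positions(construct, positions)
    codons0 = construct.codons()
    e_input = float(energy_fn(construct.cds))

    if not replaceable:  # nothing to substitute: echo the input
        notes.append("no substitutable codons; returning the input sequence")
        sol = Solution(construct.cds, e_input, 0, (), chain=-1)
        return OptimizationResult(construct, e_input, [sol], [], config, notes)

    # Pre-existing hits (e.g. in the UTRs or beyond the substitutable
    # window) cannot be removed by synonymous changes; candidates are
    # rejected only when they introduce *new* motif occurrences.
    _, input_hits = motif_filter(construct.sequence, config.forbidden_motifs)
    allowed_hits = set(input_hits)
    if allowed_hits:
        notes.append(
            "input sequence already contains forbidden motif(s) at "
            + ", ".join(f"{m}@{p}{s}" for m, p, s in sorted(allowed_hits))
            + "; only newly introduced occurrences are rejected"
        )

    def _motif_ok(full_seq: str) -> bool:
        _, hits = motif_filter(full_seq, config.forbidden_motifs)
        return set(hits) <= allowed_hits

    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(config.chains)
    best_by_cds: dict[str, Solution] = {}
    trajectories: list[list[tuple[int, float, float, bool]]] = []

    for chain in range(config.chains):
        rng = np.random.default_rng(streams[chain])
        current = list(codons0)
        e_current = e_input
        best_codons, e_best = current, e_current
        stall = 0
        traj: list[tuple[int, float, float, bool]] = []
        temperature = config.t0
        for iteration in range(config.max_iterations):
            candidate = None
            for _ in range(20):  # reject new motif violations at proposal time
                trial = propose(current, temperature, config.t0, replaceable, rng)
                full = construct.utr5 + "".join(trial) + construct.utr3
                if _motif_ok(full):
                    candidate = trial
                    break
            if candidate is None:
                traj.append((iteration, temperature, e_current, False))
                temperature *= config.cooling
                continue
            e_cand = float(energy_fn("".join(candidate)))
            accepted = metropolis_accept(
                config.badness(e_cand), config.badness(e_current), temperature, rng
            )
            if accepted:
                current, e_current = candidate, e_cand
                if config.badness(e_current) < config.badness(e_best):
                    best_codons, e_best = current, e_current
                    stall = 0
                else:
                    stall += 1
            else:
                stall += 1
            traj.append((iteration, temperature, e_cand, accepted))
            temperature *= config.cooling
            if stall >= config.patience:
                break
        trajectories.append(traj)
        cds_best = "".join(best_codons)
        n_sub, changed = _diff_stats(codons0, best_codons)
        sol = Solution(cds_best, e_best, n_sub, changed, chain)
        prev = best_by_cds.get(cds_best)
        if prev is None or config.badness(sol.energy) < config.badness(prev.energy):
            best_by_cds[cds_best] = sol

    solutions = [
        s for s in best_by_cds.values()
        if _motif_ok(construct.utr5 + s.cds + construct.utr3)
    ]
    if not solutions:
        notes.append("all candidate solutions hit forbidden motifs; "
                     "returning the input sequence")
        solutions = [Solution(construct.cds, e_input, 0, (), chain=-1)]
    solutions.sort(key=lambda s: (config.badness(s.energy), s.n_substitutions, s.cds))
    return OptimizationResult(construct, e_input, solutions, trajectories, config, notes)


def exhaustive_optimum(construct: CodingConstruct, n_codons: int | None,
                       energy_fn, limit: int = 50_000,
                       objective: str = "minimize",
                       target_energy: float | None = None) -> tuple[str, float]:
    """Global optimum by full enumeration of the synonymous search space.

    Refuses when the space (input excluded) exceeds ``limit``.
    """
    space = count_search_space(construct, n_codons)
    if space > limit:
        raise ValueError(
            f"search space of {space} variants exceeds enumeration limit {limit}"
        )
    cfg = AnnealConfig(objective=objective, target_energy=target_energy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        positions = replaceable_positions(construct, n_codons)
    codons0 = construct.codons()
    choices = [sorted(synonymous_codons(codons0[p - 1])) for p in positions]
    best_e = float(energy_fn(construct.cds))
    best_cds, best_bad = construct.cds, cfg.badness(best_e)
    for combo in itertools.product(*choices):
        trial = list(codons0)
        for pos, codon in zip(positions, combo):
            trial[pos - 1] = codon
        cds = "".join(trial)
        e = float(energy_fn(cds))
        if cfg.badness(e) < best_bad:
            best_cds, best_bad, best_e = cds, cfg.badness(e), e
    return best_cds, best_e
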