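"""Competing sequence features: CAI, tAI, codon context, G+C, and avoidance.

CAI-style scores are geometric means of per-codon relative-adaptiveness
weights; codon context is the same construction over adjacent codon pairs.
Avoidance quantifies unwanted mRNA:ncRNA hybridization: the total
interaction energy decomposes as dG_int = dG_u + dG_h (energy to open the
interacting sites plus the energy gained on hybridisation), and the score
reported here is the strongest (most negative) hybridisation component
(dG_h)_min between the mRNA region 1:30 and any ncRNA in a user-supplied
set — dG_u is computed by the engine but deliberately excluded, since it
would double-count the accessibility term scored separately.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core_seq import (
    GENETIC_CODE,
    STOP_CODONS,
    CodingConstruct,
    RegionSpec,
    normalize_sequence,
    region_sequence,
    synonymous_codons,
)

__all__ = [
    "WeightTable",
    "AvoidanceConfig",
    "InteractionResult",
    "StubInteractionEngine",
    "RNAupEngine",
    "cai",
    "tai",
    "codon_context",
    "gc_content",
    "local_gc",
    "avoidance",
    "load_packaged_table",
]


@dataclass(frozen=True)
class WeightTable:
    """Per-codon (or per-codon-pair) relative adaptiveness weights in (0, 1].

    ``kind`` is "codon" or "pair"; pair keys are written ``AAA|TTT``.
    ``source`` is a free-text citation for provenance.
    """

    name: str
    weights: dict[str, float]
    kind: str = "codon"
    source: str = ""

    def __post_init__(self) -> None:
        for key, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"{self.name}: weight for {key} is {w}, not in (0, 1]")

    def weight(self, key: str) -> float:
        try:
            return self.weights[key]
        except KeyError:
            raise KeyError(
                f"weight table {self.name!r} has no weight for {key!r}"
            ) from None

    @classmethod
    def from_codon_counts(cls, counts: dict[str, float], name: str = "cai",
                          source: str = "") -> "WeightTable":
        """Classical relative adaptiveness: w_c = f_c / max f within the family.

        ``counts`` are codon usage counts (or frequencies) from a reference
        gene set; zero-count codons get a small floor so weights stay > 0.
        """
        weights: dict[str, float] = {}
        for codon in GENETIC_CODE:
            family = synonymous_codons(codon)
            fmax = max(counts.get(c, 0.0) for c in family)
            if fmax <= 0:
                weights[codon] = 1.0
                continue
            weights[codon] = max(counts.get(codon, 0.0), 0.01 * fmax) / fmax
        return cls(name=name, weights=weights, source=source)

    @classmethod
    def read_tsv(cls, path, name: str = "", kind: str = "codon",
                 source: str = "") -> "WeightTable":
        """Read a two-column (codon/pair, weight) delimited text table."""
        weights: dict[str, float] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, value = line.split()[:2]
                if key.lower() in ("codon", "pair", "codon_pair"):
                    continue
                weights[key.upper().replace("U", "T")] = float(value)
        return cls(name=name or str(path), weights=weights, kind=kind, source=source)

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            if self.source:
                handle.write(f"# {self.name}: {self.source}\n")
            handle.write("codon\tweight\n" if self.kind == "codon" else "codon_pair\tweight\n")
            for key in sorted(self.weights):
                handle.write(f"{key}\t{self.weights[key]:.6f}\n")


def load_packaged_table(name: str) -> WeightTable:
    """Load a weight table shipped with the package (synthetic stand-ins).

    Available: ``cai_ecoli_synthetic``, ``tai_ecoli_synthetic``,
    ``cc_ecoli_synthetic``.  These are illustrative defaults generated from a
    synthetic reference gene set, not the published weight sets.
    """
    kind = "pair" if name.startswith("cc") else "codon"
    ref = resources.files("tisopt") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return WeightTable.read_tsv(path, name=name, kind=kind,
                                    source="packaged synthetic table")


def _scored_codons(cds: str) -> list[str]:
    """Codons scored by cai/tai: start codon and terminal stop excluded."""
    cds = normalize_sequence(cds)
    if len(cds) % 3:
        raise ValueError("cds length is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[0] == "ATG":
        codons = codons[1:]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} in cds")
    return codons


def _geometric_mean(values: list[float]) -> float:
    if not values:
        raise ValueError("no codons left to score")
    return float(math.exp(np.mean(np.log(values))))


def cai(cds: str, table: WeightTable) -> float:
    """Codon adaptation index: geometric mean of codon weights over the CDS.

    The start codon and terminal stop are excluded from scoring (their
    weights are fixed by definition).
    """
    return _geometric_mean([table.weight(c) for c in _scored_codons(cds)])


def tai(cds: str, table: WeightTable) -> float:
    """tRNA adaptation index; same geometric-mean construction with tAI weights."""
    return _geometric_mean([table.weight(c) for c in _scored_codons(cds)])


def codon_context(cds: str, pair_table: WeightTable) -> float:
    """Geometric mean of adjacent codon-pair weights over the full CDS.

    Unlike cai/tai this is order-sensitive: reversing the codon order changes
    the pairs and, generically, the score.
    """
    cds = normalize_sequence(cds)
    if len(cds) % 3:
        raise ValueError("cds length is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:  # stop codons carry no pair weight
        codons = codons[:-1]
    if len(codons) < 2:
        raise ValueError("codon context needs at least 2 sense codons")
    pairs = [f"{a}|{b}" for a, b in zip(codons, codons[1:])]
    return _geometric_mean([pair_table.weight(p) for p in pairs])


def gc_content(seq: str) -> float:
    """G+C content in percent."""
    seq = normalize_sequence(seq)
    return 100.0 * sum(1 for ch in seq if ch in "GC") / len(seq)


def local_gc(construct: CodingConstruct, region: RegionSpec) -> float:
    """G+C percent of the excised anchored region."""
    return gc_content(region_sequence(region, construct))


# --- mRNA:ncRNA avoidance ----------------------------------------------------

@dataclass(frozen=True)
class InteractionResult:
    """Decomposed RNA:RNA interaction energies (kcal/mol)."""

    dg_total: float
    dg_h: float  # hybridisation component
    dg_u: float  # opening component (both molecules)


class StubInteractionEngine:
    """Deterministic scripted engine for tests.

    ``script`` maps ncRNA id -> (dg_u, dg_h); unknown ids raise.
    """

    name = "stub"
    version = "scripted"

    def __init__(self, script: dict[str, tuple[float, float]]):
        self.script = dict(script)

    def interact(self, mrna_region: str, ncrna_id: str, ncrna_seq: str) -> InteractionResult:
        dg_u, dg_h = self.script[ncrna_id]
        return InteractionResult(dg_total=dg_u + dg_h, dg_h=dg_h, dg_u=dg_u)


class RNAupEngine:
    """RNAup subprocess adapter (interaction mode, ``-b -o``).

    RNAup prints the interaction as ``(total = dG_h + dG_u_long +
    dG_u_short)``; the hybridisation component is the first term.
    """

    name = "rnaup"

    def __init__(self, executable: str = "RNAup"):
        path = shutil.which(executable)
        if path is None:
            raise RuntimeError(
                f"{executable} not found on PATH; the avoidance interaction "
                "engine needs ViennaRNA's RNAup (or pass a stub engine). "
                "Adapter contract: interact(mrna_region, ncrna_id, ncrna_seq)"
                " -> InteractionResult."
            )
        self.executable = path
        try:
            out = subprocess.run([path, "--version"], capture_output=True,
                                 text=True, timeout=30)
            self.version = out.stdout.split()[-1] if out.stdout else "?"
        except Exception:
            self.version = "?"

    def interact(self, mrna_region: str, ncrna_id: str, ncrna_seq: str) -> InteractionResult:
        payload = f">mrna\n{mrna_region}\n>{ncrna_id}\n{ncrna_seq}\n"
        proc = subprocess.run(
            [self.executable, "-b", "-o"], input=payload,
            capture_output=True, text=True, timeout=300,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"RNAup failed: {proc.stderr.strip()}")
        for line in proc.stdout.splitlines():
            if "(" in line and "=" in line and "&" in line:
                inner = line[line.rfind("(") + 1 : line.rfind(")")]
                left, right = inner.split("=")
                terms = [float(t) for t in right.replace("+ ", "+").split()]
                dg_h = terms[0]
                dg_u = sum(terms[1:])
                return InteractionResult(dg_total=float(left), dg_h=dg_h, dg_u=dg_u)
        raise RuntimeError(f"could not parse RNAup output:\n{proc.stdout}")


@dataclass
class AvoidanceConfig:
    """Settings for the mRNA:ncRNA avoidance score.

    ``ncrnas`` is a non-empty list of (id, sequence) records; the default
    region 1:30 covers the first 30 nt of the CDS.
    """

    ncrnas: list[tuple[str, str]]
    region: RegionSpec = field(default_factory=lambda: RegionSpec(1, 30))
    engine: object | None = None

    def __post_init__(self) -> None:
        if not self.ncrnas:
            raise ValueError("avoidance needs a non-empty ncRNA set")


def avoidance(construct: CodingConstruct, config: AvoidanceConfig) -> float:
    """Strongest hybridisation energy (dG_h)_min against the ncRNA set, kcal/mol.

    The most negative dG_h over all mRNA:ncRNA pairs is returned; adding
    ncRNAs to the set can only keep or lower the score.
    """
    engine = config.engine or RNAupEngine()
    mrna_region = region_sequence(config.region, construct)
    best = math.inf
    for ncrna_id, ncrna_seq in config.ncrnas:
        res = engine.interact(mrna_region, ncrna_id, normalize_sequence(ncrna_seq))
        best = min(best, res.dg_h)
    return best
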