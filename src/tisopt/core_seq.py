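"""Sequence records, start-codon-anchored coordinates, codon tables and fixtures.

Coordinates throughout the package are anchored at the start codon: position
+1 is the first nucleotide of the start codon (the A of ATG), position -1 is
the nucleotide immediately upstream, and position 0 does not exist.  Regions
are written ``start:end`` with inclusive ends, e.g. ``-24:24`` is the 48-nt
window spanning 24 nt of 5'UTR and the first 24 nt of the coding sequence.
Internally every region is bridged to a zero-based half-open offset interval
into the concatenated ``utr5 + cds + utr3`` transcript.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodingConstruct",
    "RegionSpec",
    "CodonTable",
    "LabeledDataset",
    "STANDARD_TABLE",
    "normalize_sequence",
    "translate",
    "region_length",
    "endpos_len_to_region",
    "region_to_offsets",
    "synonymous_codons",
    "read_fasta",
    "write_fasta",
    "random_construct",
    "labeled_fixture",
]

_VALID = set("ACGT")


class SequenceError(ValueError):
    """Raised for malformed nucleotide input."""


def normalize_sequence(raw: str) -> str:
    """Normalize raw nucleotide text to the internal DNA alphabet.

    Case-folds, maps U to T and strips whitespace.  Any other character is a
    validation error naming the (1-based) offending position in the stripped
    sequence.
    """
    if not raw or not raw.strip():
        raise SequenceError("empty sequence")
    seq = "".join(raw.split()).upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos}: "
                "expected A, C, G, T or U"
            )
    return seq


# --- genetic code (translation table 1), via Biopython -----------------------

_std = _BioCodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (one-letter), 61 sense codons
GENETIC_CODE: dict[str, str] = dict(_std.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_std.stop_codons)

_SYN: dict[str, frozenset[str]] = {}
for _aa in set(GENETIC_CODE.values()):
    _family = frozenset(c for c, a in GENETIC_CODE.items() if a == _aa)
    for _c in _family:
        _SYN[_c] = _family


@dataclass(frozen=True)
class CodonTable:
    """Standard genetic code with synonymous-codon families.

    ``forward`` maps each of the 61 sense codons to its amino acid;
    ``families`` maps each amino acid to its synonymous codon set.  The
    families partition the sense codons.
    """

    forward: dict[str, str] = field(default_factory=lambda: dict(GENETIC_CODE))
    stops: frozenset[str] = STOP_CODONS

    @property
    def families(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for codon, aa in self.forward.items():
            out.setdefault(aa, frozenset())
        for aa in out:
            out[aa] = frozenset(c for c, a in self.forward.items() if a == aa)
        return out


STANDARD_TABLE = CodonTable()


def synonymous_codons(codon: str) -> frozenset[str]:
    """All codons encoding the same amino acid as ``codon`` (input included).

    Stop codons are not substitutable and raise.
    """
    codon = normalize_sequence(codon)
    if len(codon) != 3:
        raise SequenceError(f"not a codon: {codon!r}")
    if codon in STOP_CODONS:
        raise SequenceError(f"stop codon {codon} is not substitutable")
    return _SYN[codon]


def translate(cds: str) -> str:
    """Translate a CDS (standard code); stop codons render as ``*``."""
    return str(Seq(cds).translate())


@dataclass
class CodingConstruct:
    """A 5'UTR + CDS (+ optional 3'UTR) record anchored at the start codon."""

    id: str
    utr5: str
    cds: str
    utr3: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.utr5 = normalize_sequence(self.utr5) if self.utr5 else ""
        self.cds = normalize_sequence(self.cds)
        self.utr3 = normalize_sequence(self.utr3) if self.utr3 else ""
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise SequenceError(
                f"{self.id}: cds length {len(self.cds)} is not a positive "
                "multiple of 3"
            )

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    def is_canonical(self, require_stop: bool = False) -> bool:
        """True if the CDS begins with ATG (and, optionally, ends on a stop)."""
        if not self.cds.startswith("ATG"):
            return False
        if require_stop and self.cds[-3:] not in STOP_CODONS:
            return False
        return True

    def assert_canonical(self, require_stop: bool = False) -> None:
        if not self.cds.startswith("ATG"):
            raise SequenceError(f"{self.id}: cds does not begin with ATG")
        if require_stop and self.cds[-3:] not in STOP_CODONS:
            raise SequenceError(f"{self.id}: cds does not end with a stop codon")

    def with_cds(self, cds: str, id: str | None = None) -> "CodingConstruct":
        return dataclasses.replace(self, cds=cds, id=id or self.id)

    def protein(self) -> str:
        return translate(self.cds)


@dataclass(frozen=True, order=False)
class RegionSpec:
    """Start-codon-anchored inclusive region ``start:end`` (no position 0)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise ValueError("anchored coordinates have no position 0")
        if _rank(self.start) > _rank(self.end):
            raise ValueError(f"region start {self.start} is after end {self.end}")

    def __str__(self) -> str:
        return f"{self.start}:{self.end}"

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``start:end`` notation, e.g. ``-24:24``."""
        try:
            start_s, end_s = text.split(":")
            return cls(int(start_s), int(end_s))
        except ValueError as exc:
            raise ValueError(f"cannot parse region {text!r}: {exc}") from exc


def _rank(coord: int) -> int:
    """Map an anchored coordinate onto the integers with 0 removed."""
    return coord if coord > 0 else coord + 1


def region_length(region: RegionSpec) -> int:
    """Length in nt of an anchored region (position 0 does not exist)."""
    if (region.start > 0) == (region.end > 0):
        return region.end - region.start + 1
    return region.end - region.start


def endpos_len_to_region(i: int, l: int) -> RegionSpec:
    """Region of length ``l`` whose last nucleotide sits at anchored position ``i``.

    This is the (i, l) parametrisation used for opening-energy scans: e.g.
    (10, 10) is region 1:10 and (24, 48) is region -24:24.
    """
    if i == 0:
        raise ValueError("anchored coordinates have no position 0")
    if l < 1:
        raise ValueError(f"length must be >= 1, got {l}")
    start = i - l + 1
    if i > 0 and start <= 0:
        start -= 1
    return RegionSpec(start, i)


def region_to_offsets(region: RegionSpec, construct: CodingConstruct) -> tuple[int, int]:
    """Bridge an anchored region to a zero-based half-open transcript interval.

    Offset 0 is the first nucleotide of ``utr5``; the start codon begins at
    offset ``len(utr5)``.  Raises if the region extends beyond the available
    flanks, stating how many nt are missing.
    """
    n5 = len(construct.utr5)
    total = len(construct.sequence)

    def off(coord: int) -> int:
        return n5 + coord - 1 if coord > 0 else n5 + coord

    lo, hi = off(region.start), off(region.end) + 1
    if lo < 0:
        raise IndexError(
            f"region {region} extends {-lo} nt past the available 5' flank "
            f"({n5} nt of 5'UTR)"
        )
    if hi > total:
        raise IndexError(
            f"region {region} extends {hi - total} nt past the available "
            f"3' end ({total} nt total)"
        )
    return lo, hi


def region_sequence(region: RegionSpec, construct: CodingConstruct) -> str:
    """Excise the nucleotide sequence covered by an anchored region."""
    lo, hi = region_to_offsets(region, construct)
    return construct.sequence[lo:hi]


# --- FASTA I/O ---------------------------------------------------------------

def read_fasta(path: str | os.PathLike | io.TextIOBase,
               utr5_len: int = 0, utr3_len: int = 0) -> list[CodingConstruct]:
    """Read a multi-record FASTA into :class:`CodingConstruct` records.

    The first ``utr5_len`` nt of each record become the 5'UTR and the last
    ``utr3_len`` nt the 3'UTR; the remainder is the CDS.  Sequences are
    normalized (U -> T, case-folded).  Empty files and duplicate ids are
    errors.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[CodingConstruct] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        if utr5_len + utr3_len >= len(seq):
            raise SequenceError(
                f"{rec.id}: UTR lengths ({utr5_len}+{utr3_len}) leave no CDS "
                f"in a {len(seq)} nt record"
            )
        utr5 = seq[:utr5_len]
        utr3 = seq[len(seq) - utr3_len :] if utr3_len else ""
        cds = seq[utr5_len : len(seq) - utr3_len or None]
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        out.append(CodingConstruct(rec.id, utr5, cds, utr3, description=desc))
    return out


def write_fasta(records: list[CodingConstruct], path: str | os.PathLike) -> None:
    """Write constructs as DNA FASTA, wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(c.sequence), id=c.id, description=c.description)
        for c in records
    ]
    SeqIO.write(seqrecs, path, "fasta")


# --- fixture generators ------------------------------------------------------

_SENSE = sorted(GENETIC_CODE)
_STOPS = sorted(STOP_CODONS)


def random_construct(n_codons: int, utr5_len: int = 24,
                     seed: int | np.random.Generator | None = None,
                     utr3_len: int = 0) -> CodingConstruct:
    """Deterministic random canonical construct for tests and demos.

    ``cds`` is ATG + ``n_codons - 2`` random sense codons + a random stop;
    the 5'UTR is uniform random nucleotides.
    """
    if n_codons < 2:
        raise ValueError("need at least start + stop codons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    body = "".join(rng.choice(_SENSE) for _ in range(n_codons - 2))
    cds = "ATG" + body + rng.choice(_STOPS)
    utr5 = "".join(rng.choice(list("ACGT"), size=utr5_len)) if utr5_len else ""
    utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len)) if utr3_len else ""
    return CodingConstruct(f"random-{n_codons}c", utr5, cds, utr3)


@dataclass
class LabeledDataset:
    """Records of (opening energy, binary expression outcome).

    ``outcome`` is 1 for expression success, 0 for failure.  ``metadata``
    records how a synthetic dataset was generated.
    """

    ids: list[str]
    opening_energy: np.ndarray
    outcome: np.ndarray
    sequences: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.opening_energy = np.asarray(self.opening_energy, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.opening_energy.shape != self.outcome.shape:
            raise ValueError("opening_energy and outcome lengths differ")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcomes must be binary 0/1")

    def __len__(self) -> int:
        return len(self.outcome)

    @property
    def n_success(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_failure(self) -> int:
        return int(len(self) - self.outcome.sum())

    def require_both_classes(self) -> None:
        if self.n_success == 0 or self.n_failure == 0:
            raise ValueError("dataset contains a single outcome class")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": self.ids, "opening_energy": self.opening_energy,
             "outcome": self.outcome}
        )

    @classmethod
    def from_frame(cls, frame, metadata: dict | None = None) -> "LabeledDataset":
        cols = {c.lower(): c for c in frame.columns}
        if "outcome" not in cols:
            raise ValueError("labeled table needs an 'outcome' column")
        ids = (
            [str(x) for x in frame[cols["id"]]]
            if "id" in cols
            else [str(i) for i in range(len(frame))]
        )
        if "opening_energy" not in cols:
            raise ValueError("labeled table needs an 'opening_energy' column")
        return cls(
            ids=ids,
            opening_energy=frame[cols["opening_energy"]].to_numpy(dtype=float),
            outcome=frame[cols["outcome"]].to_numpy(dtype=int),
            metadata=metadata or {},
        )


def labeled_fixture(n: int, seed: int | None = None, *, slope: float = 0.5,
                    midpoint: float = 12.0, energy_low: float = 2.0,
                    energy_high: float = 30.0) -> LabeledDataset:
    """Synthetic success/failure dataset with a logistic label model.

    Opening energies are uniform on [energy_low, energy_high]; the success
    probability decreases logistically with opening energy,
    ``p(x) = 1 / (1 + exp(slope * (x - midpoint)))``, so ``slope = 0`` makes
    labels independent of energy (p = 1/2) and large slopes approach perfect
    separation at ``midpoint``.  Generator parameters are recorded in
    ``metadata``.
    """
    if n < 20:
        raise ValueError("need n >= 20 records")
    rng = np.random.default_rng(seed)
    x = rng.uniform(energy_low, energy_high, size=n)
    p = 1.0 / (1.0 + np.exp(slope * (x - midpoint)))
    y = (rng.random(n) < p).astype(int)
    return LabeledDataset(
        ids=[f"s{i}" for i in range(n)],
        opening_energy=x,
        outcome=y,
        metadata={
            "generator": "labeled_fixture",
            "n": n,
            "seed": seed,
            "slope": slope,
            "midpoint": midpoint,
            "energy_low": energy_low,
            "energy_high": energy_high,
        },
    )
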