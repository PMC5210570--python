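"""Shared domain types for the toolkit.

Conventions used throughout:

* residue coordinates are **1-based and inclusive** (CATH segment style);
* structural similarity scores live on a 0-100 scale with ``score(a, a) == 100``;
* profile-profile scores are expressed in bits;
* percentages are plain numbers in ``[0, 100]``, never fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class ParseError(ValueError):
    """Raised when a textual record cannot be parsed; names the offence."""


# ---------------------------------------------------------------------------
# identifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class DomainID:
    """Seven-character domain identifier: 4-char structure code + chain + 2-digit number.

    Example: ``1ct9C02`` is domain 2 of chain C in structure 1ct9.
    """

    structure_code: str
    chain: str
    domain_number: int

    def __post_init__(self) -> None:
        if len(self.structure_code) != 4 or not self.structure_code.isalnum():
            raise ParseError(
                f"structure code {self.structure_code!r} must be 4 alphanumeric characters"
            )
        if len(self.chain) != 1:
            raise ParseError(f"chain {self.chain!r} must be a single character")
        if not 0 <= self.domain_number <= 99:
            raise ParseError(f"domain number {self.domain_number} outside 0-99")

    def render(self) -> str:
        return f"{self.structure_code}{self.chain}{self.domain_number:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_domain_id(text: str) -> DomainID:
    """Parse a 7-character domain identifier such as ``1ct9C02``."""
    if len(text) != 7:
        raise ParseError(f"domain ID {text!r} has length {len(text)}, expected 7")
    code, chain, num = text[:4], text[4], text[5:]
    if not code.isalnum():
        bad = next(i for i, c in enumerate(code) if not c.isalnum())
        raise ParseError(f"domain ID {text!r}: non-alphanumeric structure code at position {bad}")
    if not num.isdigit():
        raise ParseError(f"domain ID {text!r}: positions 5-6 must be digits, got {num!r}")
    return DomainID(code, chain, int(num))


@dataclass(frozen=True, order=True)
class CathCode:
    """Hierarchical C.A.T.H classification code.

    Populated levels form a contiguous prefix: ``C``, ``C.A``, ``C.A.T`` or
    ``C.A.T.H``.  ``3.40.50.620`` names a homologous superfamily; ``3.40.50``
    its fold (topology).
    """

    class_id: int
    arch_id: Optional[int] = None
    topol_id: Optional[int] = None
    homol_id: Optional[int] = None

    def __post_init__(self) -> None:
        levels = (self.class_id, self.arch_id, self.topol_id, self.homol_id)
        seen_none = False
        for value in levels:
            if value is None:
                seen_none = True
            elif seen_none:
                raise ParseError(f"CATH code levels must be a contiguous prefix, got {levels}")
            elif value <= 0:
                raise ParseError(f"CATH code levels must be positive integers, got {value}")

    @property
    def depth(self) -> int:
        return sum(v is not None for v in (self.class_id, self.arch_id, self.topol_id, self.homol_id))

    def levels(self) -> tuple[int, ...]:
        return tuple(
            v for v in (self.class_id, self.arch_id, self.topol_id, self.homol_id) if v is not None
        )

    def prefix(self, depth: int) -> "CathCode":
        """The ancestor code truncated to ``depth`` levels (1=C ... 4=H)."""
        if not 1 <= depth <= self.depth:
            raise ValueError(f"depth {depth} outside 1..{self.depth}")
        vals: list[Optional[int]] = list(self.levels()[:depth]) + [None] * (4 - depth)
        return CathCode(*vals)  # type: ignore[arg-type]

    def same_at_level(self, other: "CathCode", depth: int) -> bool:
        """True iff both codes are populated to ``depth`` and agree on every level up to it."""
        if self.depth < depth or other.depth < depth:
            return False
        return self.levels()[:depth] == other.levels()[:depth]

    def is_prefix_of(self, other: "CathCode") -> bool:
        return other.depth >= self.depth and other.levels()[: self.depth] == self.levels()

    def render(self) -> str:
        return ".".join(str(v) for v in self.levels())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_cath_code(text: str) -> CathCode:
    """Parse a dot-separated CATH code with 1-4 integer levels, e.g. ``3.40.50.620``."""
    fields = text.split(".")
    if not 1 <= len(fields) <= 4:
        raise ParseError(f"CATH code {text!r} has {len(fields)} fields, expected 1-4")
    values: list[int] = []
    for pos, piece in enumerate(fields):
        if not piece.isdigit() or int(piece) <= 0:
            raise ParseError(f"CATH code {text!r}: field {pos + 1} ({piece!r}) is not a positive integer")
        values.append(int(piece))
    padded: list[Optional[int]] = values + [None] * (4 - len(values))
    return CathCode(*padded)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Segment:
    """Contiguous residue range, 1-based inclusive."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ParseError(f"segment start {self.start} must be >= 1")
        if self.start > self.stop:
            raise ParseError(f"segment {self.start}-{self.stop}: start > stop")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.stop + 1)

    def render(self) -> str:
        return f"{self.start}-{self.stop}"


@dataclass(frozen=True)
class DomainRegion:
    """Possibly discontiguous domain footprint: sorted, non-overlapping segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ParseError("domain region needs at least one segment")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.stop:
                raise ParseError(
                    f"segments {prev.render()} and {cur.render()} overlap or are unsorted"
                )

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def residues(self) -> Iterator[int]:
        for seg in self.segments:
            yield from seg.residues()

    def residue_set(self) -> frozenset[int]:
        return frozenset(self.residues())

    def overlaps(self, other: "DomainRegion") -> bool:
        for a in self.segments:
            for b in other.segments:
                if a.start <= b.stop and b.start <= a.stop:
                    return True
        return False

    def render(self) -> str:
        return ",".join(s.render() for s in self.segments)


def parse_region(text: str) -> DomainRegion:
    """Parse a segment string like ``1-100`` or ``1-100,150-200``."""
    segments = []
    for piece in text.split(","):
        left, sep, right = piece.partition("-")
        if not sep or not left.strip().isdigit() or not right.strip().isdigit():
            raise ParseError(f"malformed segment {piece!r} in {text!r}")
        segments.append(Segment(int(left), int(right)))
    return DomainRegion(tuple(sorted(segments)))


# ---------------------------------------------------------------------------
# structures, alignments, hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    label: str
    ca: tuple[float, float, float]
    cb: Optional[tuple[float, float, float]] = None
    aa: str = "A"


@dataclass
class Structure:
    """Ordered CA (optionally CB) trace of a single domain."""

    name: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        arr = np.array([r.ca for r in self.residues], dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(f"structure {self.name}: non-finite coordinates")
        return arr

    def cb_coords(self) -> np.ndarray:
        """CB per residue, falling back to CA where CB is absent (incl. glycine)."""
        return np.array([r.cb if r.cb is not None else r.ca for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class MSA:
    """Multiple sequence alignment: equal-length rows over the 20 amino acids + '-'."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ParseError("MSA has no rows")
        width = len(self.rows[0][1])
        if width < 1:
            raise ParseError("MSA rows are empty")
        for name, seq in self.rows:
            if len(seq) != width:
                raise ParseError(f"MSA row {name!r} has length {len(seq)}, expected {width}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)

    def ids(self) -> list[str]:
        return [name for name, _ in self.rows]


@dataclass(frozen=True)
class HitRecord:
    """One domain hit on a query protein."""

    query_id: str
    match_id: str
    score: float
    region: DomainRegion

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ParseError(f"hit {self.match_id}: negative score {self.score}")


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


@dataclass
class Thresholds:
    """All protocol cut-offs in one place; every field can be overridden.

    Defaults follow the production assignment protocol: an SVM decision value
    of at least 3.47 with at least 70% structural overlap assigns a domain to
    an existing superfamily; failing that, a structural score of at least 70
    with at least 60% overlap creates a new superfamily within the matched
    fold.  A profile-profile score strictly above 10 bits draws a network
    edge; a DOPs score of at least 70 freezes a functional family; a domain
    whose boundaries overlap a previous version by less than 70% is remapped.
    """

    svm_decision: float = 3.47
    svm_overlap_min_pct: float = 70.0
    ssap_fallback_score_min: float = 70.0
    ssap_fallback_overlap_min_pct: float = 60.0
    prc_edge_min: float = 10.0
    dops_frozen_min: float = 70.0
    version_map_overlap_min_pct: float = 70.0
    naming_redundancy_identity_pct: float = 95.0
    easy_positive_ssap_max: float = 80.0
    easy_positive_identity_pct: float = 35.0

    def __post_init__(self) -> None:
        for name in (
            "svm_overlap_min_pct",
            "ssap_fallback_overlap_min_pct",
            "version_map_overlap_min_pct",
            "naming_redundancy_identity_pct",
            "easy_positive_identity_pct",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise ValueError(f"{name}={value} outside [0, 100]")


@dataclass(frozen=True)
class ProfileModel:
    """Per-column amino-acid emission distributions plus a background.

    ``columns`` has shape (L, 20) in the order ``ACDEFGHIKLMNPQRSTVWY``; each
    row sums to 1.  ``background`` is the null emission distribution the
    log-odds scores are taken against.
    """

    columns: np.ndarray
    background: np.ndarray
    n_seqs_source: int = 1
    name: str = "profile"

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "background", bg)
        if cols.ndim != 2 or cols.shape[1] != 20 or cols.shape[0] < 1:
            raise ValueError(f"profile columns have shape {cols.shape}, expected (L>=1, 20)")
        if np.any(cols < 0) or not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must be distributions summing to 1")
        if bg.shape != (20,) or np.any(bg < 0):
            raise ValueError("background must be a length-20 non-negative vector")

    @property
    def n_columns(self) -> int:
        return int(self.columns.shape[0])


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)
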