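"""Seeded synthetic inputs for every computation in the toolkit.

Nothing here is downloaded or physically realistic: structures are ideal
helix/strand backbones with controlled Gaussian noise, sequences are random
strings with controlled mutation rates, and alignments are built column by
column to hit requested conservation values.  What the generators *do*
guarantee is the statistical shape the analyses assume — a four-level
classification hierarchy whose structural similarity decays with distance
in the hierarchy, superfamily members that are remote homologues (moderate
structural similarity, low sequence identity, as in a benchmark purged of
easy positives), and bit-identical reproducibility for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import AMINO_ACIDS, CathCode, DomainID, MSA, Residue, Structure

FOLD_KINDS = ("helix", "strand", "helix_bundle", "beta_meander")


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def _helix_coords(length: int) -> np.ndarray:
    # alpha-helix-like: 1.5 A rise, 100 deg twist, 2.3 A radius
    theta = np.deg2rad(100.0) * np.arange(length)
    return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(length)], axis=1)


def _strand_coords(length: int) -> np.ndarray:
    # extended strand: 3.3 A rise with a lateral zigzag
    i = np.arange(length)
    return np.stack([3.3 * i, 0.9 * (-1.0) ** i, np.zeros(length)], axis=1)


def _helix_bundle_coords(length: int) -> np.ndarray:
    half = (length + 1) // 2
    up = _helix_coords(half)
    down = _helix_coords(length - half)
    down = down * np.array([1.0, -1.0, -1.0]) + np.array([10.0, 1.0, up[-1, 2] + 1.5])
    return np.vstack([up, down])


def _beta_meander_coords(length: int) -> np.ndarray:
    strand_len = 6
    coords = []
    for i in range(length):
        strand, pos = divmod(i, strand_len)
        x = 3.3 * pos if strand % 2 == 0 else 3.3 * (strand_len - 1 - pos)
        coords.append([x, 4.8 * strand + 0.4 * (-1.0) ** i, 0.7 * (-1.0) ** (i + strand)])
    return np.array(coords)


_BUILDERS = {
    "helix": _helix_coords,
    "strand": _strand_coords,
    "helix_bundle": _helix_bundle_coords,
    "beta_meander": _beta_meander_coords,
}


def make_toy_structure(
    kind: str,
    length: int = 24,
    noise_sigma: float = 0.0,
    seed: int = 0,
    name: Optional[str] = None,
    sequence: Optional[str] = None,
) -> Structure:
    """Ideal-geometry backbone of the given fold kind plus isotropic noise."""
    if kind not in _BUILDERS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {FOLD_KINDS}")
    if length < 3:
        raise ValueError("need length >= 3")
    rng = np.random.default_rng(seed)
    coords = _BUILDERS[kind](length).astype(float)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    seq = sequence or "".join(rng.choice(list(AMINO_ACIDS), size=length))
    residues = [
        Residue(label=str(i + 1), ca=tuple(coords[i]), cb=None, aa=seq[i]) for i in range(length)
    ]
    return Structure(name or f"{kind}{length}", residues)


def rigid_transform(structure: Structure, seed: int = 0, name: Optional[str] = None) -> Structure:
    """A randomly rotated and translated copy (for invariance checks)."""
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.normal(0.0, 20.0, 3)
    residues = []
    for res in structure.residues:
        ca = tuple(q @ np.array(res.ca) + shift)
        cb = tuple(q @ np.array(res.cb) + shift) if res.cb is not None else None
        residues.append(Residue(res.label, ca, cb, res.aa))
    return Structure(name or f"{structure.name}_moved", residues)


# ---------------------------------------------------------------------------
# classification hierarchy
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Shape and noise model of a synthetic classification hierarchy.

    Noise scales (Å, applied cumulatively down the hierarchy) are chosen so
    that superfamily members are *remote* homologues: structurally similar
    but below the easy-positive structural cut-off, with ~15% sequence
    identity.  ``member_sigma`` perturbs each member around its superfamily
    template, ``superfam_sigma`` each superfamily template around its
    topology template, and ``topology_sigma`` each topology template around
    the ideal fold geometry.
    """

    seed: int = 0
    n_classes: int = 2
    archs_per_class: int = 2
    topols_per_arch: int = 2
    superfams_per_topol: int = 2
    domains_per_superfam: int = 3
    base_length: int = 22
    length_step: int = 6
    member_sigma: float = 0.8
    superfam_sigma: float = 2.5
    topology_sigma: float = 3.5
    member_trim_max: int = 2
    mutation_prob: float = 0.85


@dataclass
class Hierarchy:
    classification: dict[DomainID, CathCode]
    structures: dict[DomainID, Structure]
    sequences: dict[DomainID, str]

    def domains(self) -> list[DomainID]:
        return sorted(self.classification)


def make_hierarchy(spec: FixtureSpec) -> Hierarchy:
    """Synthetic C.A.T.H hierarchy with one template structure per level.

    Classes alternate helix- and strand-based fold kinds; architectures
    within a class differ in length; topologies carry an individual random
    deformation; superfamily templates perturb their topology template; and
    members are noisy, terminally trimmed, heavily mutated copies of their
    superfamily template.
    """
    rng = np.random.default_rng(spec.seed)
    classification: dict[DomainID, CathCode] = {}
    structures: dict[DomainID, Structure] = {}
    sequences: dict[DomainID, str] = {}
    serial = 0
    for c in range(1, spec.n_classes + 1):
        kinds = ("helix", "helix_bundle") if c % 2 == 1 else ("strand", "beta_meander")
        for a in range(1, spec.archs_per_class + 1):
            length = spec.base_length + spec.length_step * (a - 1)
            for t in range(1, spec.topols_per_arch + 1):
                kind = kinds[(t - 1) % 2]
                ideal = _BUILDERS[kind](length + 2 * spec.member_trim_max)
                topo_template = ideal + rng.normal(0.0, spec.topology_sigma, ideal.shape)
                for h in range(1, spec.superfams_per_topol + 1):
                    sf_template = topo_template + rng.normal(0.0, spec.superfam_sigma, topo_template.shape)
                    sf_sequence = "".join(rng.choice(list(AMINO_ACIDS), size=len(sf_template)))
                    for d in range(1, spec.domains_per_superfam + 1):
                        serial += 1
                        dom_id = DomainID(f"{serial:04d}", "A", 1)
                        coords = sf_template + rng.normal(0.0, spec.member_sigma, sf_template.shape)
                        start = int(rng.integers(0, spec.member_trim_max + 1))
                        stop = len(coords) - int(rng.integers(0, spec.member_trim_max + 1))
                        seq = _mutate(sf_sequence, spec.mutation_prob, rng)[start:stop]
                        residues = [
                            Residue(str(i + 1), tuple(coords[j]), None, seq[i])
                            for i, j in enumerate(range(start, stop))
                        ]
                        classification[dom_id] = CathCode(c, a, t, h)
                        structures[dom_id] = Structure(dom_id.render(), residues)
                        sequences[dom_id] = seq
    return Hierarchy(classification, structures, sequences)


def _mutate(seq: str, prob: float, rng: np.random.Generator) -> str:
    out = []
    for aa in seq:
        if rng.random() < prob:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# alignments with target conservation
# ---------------------------------------------------------------------------


def _column_for_target(target: float, depth: int) -> tuple[np.ndarray, float]:
    """Integer residue counts whose conservation is closest to ``target``.

    Searches compositions with one dominant residue and the remainder spread
    as evenly as possible over k other residue types.
    """
    best: tuple[float, np.ndarray, float] | None = None
    for dominant in range(depth, 0, -1):
        rest = depth - dominant
        for k in range(0, 20 if rest else 1):
            counts = np.zeros(20, dtype=int)
            counts[0] = dominant
            if rest:
                if k == 0:
                    continue
                base, extra = divmod(rest, k)
                for idx in range(k):
                    counts[1 + idx] = base + (1 if idx < extra else 0)
            freqs = counts[counts > 0] / depth
            entropy = float(-(freqs * np.log(freqs)).sum())
            score = 1.0 - entropy / math.log(20.0)
            gap = abs(score - target)
            if best is None or gap < best[0]:
                best = (gap, counts, score)
    assert best is not None
    return best[1], best[2]


def make_msa_with_conservation(
    pattern: Sequence[float], depth: int = 50, seed: int = 0
) -> MSA:
    """Alignment whose column conservation scores approximate ``pattern``.

    Each target in [0, 1] is realised within ±0.05 (gap-free columns,
    conservation achieved through residue composition); the row order of
    residues within a column is shuffled per seed, which leaves conservation
    unchanged.  Residue identities rotate per column so identical targets
    still produce distinct columns.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    columns = []
    for j, target in enumerate(pattern):
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target conservation {target} outside [0, 1]")
        counts, achieved = _column_for_target(float(target), depth)
        if abs(achieved - target) > 0.05:
            raise ValueError(
                f"cannot realise conservation {target} within 0.05 at depth {depth} "
                f"(closest achievable: {achieved:.3f})"
            )
        residues = []
        for slot, count in enumerate(counts):
            aa = AMINO_ACIDS[(slot + j) % 20]  # rotate identities per column
            residues.extend([aa] * int(count))
        rng.shuffle(residues)
        columns.append(residues)
    rows = [
        (f"seq{i + 1}", "".join(col[i] for col in columns)) for i in range(depth)
    ]
    return MSA(rows)


# ---------------------------------------------------------------------------
# description sets
# ---------------------------------------------------------------------------


def make_description_set(
    vocab: Sequence[str],
    n: int,
    redundancy_fraction: float = 0.0,
    seed: int = 0,
    seq_length: int = 60,
) -> list[tuple[str, str, str]]:
    """(ID, description, sequence) triples with controlled redundancy.

    A ``redundancy_fraction`` of the sequences are near-copies of earlier
    ones (> 95% identity: one substitution); the rest are independent random
    sequences (pairwise identity far below 95%).  Descriptions are 2-3 word
    phrases drawn from ``vocab``.
    """
    if not vocab:
        raise ValueError("empty vocabulary")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    for i in range(n):
        words = rng.choice(list(vocab), size=int(rng.integers(2, 4)), replace=True)
        description = " ".join(words)
        if records and rng.random() < redundancy_fraction:
            template = records[int(rng.integers(0, len(records)))][2]
            pos = int(rng.integers(0, len(template)))
            replacement = AMINO_ACIDS[int(rng.integers(0, 20))]
            seq = template[:pos] + replacement + template[pos + 1 :]
        else:
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=seq_length))
        records.append((f"s{i + 1:03d}", description, seq))
    return records
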