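"""Readers and writers for the standard formats the toolkit consumes.

PDB coordinate files are read through Biopython's ``Bio.PDB``; alignments
through ``Bio.AlignIO`` (aligned FASTA and Stockholm); HMMER3 domain tables
through ``Bio.SearchIO``; HMMER3 ASCII ``.hmm`` profiles through ``pyhmmer``.
Two small plain-text dialects are this package's own and round-trip exactly:

* the hits TSV — four tab-separated columns ``query_id  match_id  score
  segments`` where segments is ``s1-e1[,s2-e2...]`` (1-based inclusive);
* the profile table — a header line, a background line, then one line of 20
  tab-separated emission probabilities per column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
from Bio import AlignIO, SearchIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .types import (
    GAP,
    AMINO_ACIDS,
    DomainRegion,
    HitRecord,
    MSA,
    ParseError,
    ProfileModel,
    Residue,
    Structure,
    parse_region,
    uniform_background,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def read_structure(
    path: PathLike,
    chain_filter: Optional[str] = None,
    region_filter: Optional[DomainRegion] = None,
    name: Optional[str] = None,
) -> Structure:
    """Read a CA/CB trace from a PDB-format file.

    Residues are ordered by (chain id, residue number, insertion code); only
    ATOM residues carrying a CA atom are kept.  ``region_filter`` selects by
    the residue sequence numbers written in the file (1-based inclusive).
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(name or Path(path).stem, str(path)).get_models())
    wanted = region_filter.residue_set() if region_filter is not None else None
    picked = []
    for chain in model:
        if chain_filter is not None and chain.id != chain_filter:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():  # HETATM / water
                continue
            if wanted is not None and resseq not in wanted:
                continue
            if "CA" not in res:
                continue
            ca = tuple(float(x) for x in res["CA"].coord)
            cb = tuple(float(x) for x in res["CB"].coord) if "CB" in res else None
            aa = protein_letters_3to1.get(res.get_resname().strip().upper(), "X")
            picked.append(((chain.id, resseq, icode), Residue(f"{chain.id}{resseq}{icode.strip()}", ca, cb, aa)))
    if not picked:
        raise ParseError(f"{path}: no residues selected (no ATOM records with CA in selection)")
    picked.sort(key=lambda item: item[0])
    residues = [r for _, r in picked]
    for res in residues:
        if not all(math.isfinite(v) for v in res.ca):
            raise ParseError(f"{path}: unreadable coordinates at residue {res.label}")
    return Structure(name or Path(path).stem, residues)


def write_structure(structure: Structure, path: PathLike, chain: str = "A") -> None:
    """Write a minimal single-chain PDB file (CA and, where present, CB atoms)."""
    lines = []
    serial = 1
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    for i, res in enumerate(structure.residues, start=1):
        resname = one_to_three.get(res.aa, "ALA")
        for atom_name, coord in (("CA", res.ca), ("CB", res.cb)):
            if coord is None:
                continue
            x, y, z = coord
            lines.append(
                f"ATOM  {serial:5d}  {atom_name:<3s}{resname:>4s} {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom_name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_MSA_FORMATS = {"fasta": "fasta", "afa": "fasta", "stockholm": "stockholm", "sto": "stockholm"}


def read_msa(path: PathLike, format: str = "fasta") -> MSA:
    """Read an aligned FASTA or Stockholm alignment into an :class:`MSA`."""
    try:
        fmt = _MSA_FORMATS[format.lower()]
    except KeyError:
        raise ParseError(f"unknown MSA format {format!r}; expected fasta or stockholm") from None
    alignment = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in alignment]
    msa = MSA(rows)
    alphabet = set(AMINO_ACIDS + GAP + "X")
    for rec_id, seq in msa.rows:
        bad = set(seq) - alphabet
        if bad:
            raise ParseError(f"MSA row {rec_id!r} contains unexpected symbols {sorted(bad)}")
    return msa


def write_msa(msa: MSA, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.rows:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------


def read_hits(path: PathLike, dialect: str = "tsv") -> list[HitRecord]:
    """Read domain hits: ``tsv`` (native dialect) or ``domtblout`` (HMMER3 hmmscan).

    domtblout hits use the **envelope** coordinates and the per-domain bit
    score, matching common architecture-resolution practice.
    """
    if dialect == "tsv":
        return _read_hits_tsv(path)
    if dialect == "domtblout":
        return _read_hits_domtblout(path)
    raise ParseError(f"unknown hits dialect {dialect!r}; expected tsv or domtblout")


def _read_hits_tsv(path: PathLike) -> list[HitRecord]:
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        query_id, match_id, score_text, segments = fields
        try:
            score = float(score_text)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed score {score_text!r}") from None
        hits.append(HitRecord(query_id, match_id, score, parse_region(segments)))
    return hits


def _read_hits_domtblout(path: PathLike) -> list[HitRecord]:
    hits = []
    for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
        for hit in qresult:
            for hsp in hit:
                region = parse_region(f"{hsp.env_start + 1}-{hsp.env_end}")
                hits.append(HitRecord(qresult.id, hit.id, float(hsp.bitscore), region))
    return hits


def write_hits(hits: Iterable[HitRecord], destination: Union[PathLike, TextIO]) -> None:
    """Write hits in the native TSV dialect (round-trips through ``read_hits``)."""
    lines = [
        f"{h.query_id}\t{h.match_id}\t{h.score:g}\t{h.region.render()}" for h in hits
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
    else:
        Path(destination).write_text(text)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def read_profile(path: PathLike) -> ProfileModel:
    """Read a profile: HMMER3 ASCII ``.hmm`` or the native profile table.

    For ``.hmm`` files only the match-state emissions are used; insert states
    and transition probabilities are discarded.
    """
    path = Path(path)
    if path.suffix == ".hmm":
        return _read_hmm(path)
    return _read_profile_table(path)


def _read_hmm(path: Path) -> ProfileModel:
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        hmm = fh.read()
    if hmm is None:
        raise ParseError(f"{path}: no HMM found")
    symbols = hmm.alphabet.symbols[: hmm.alphabet.K]
    if symbols != AMINO_ACIDS:
        raise ParseError(f"{path}: unsupported alphabet {symbols!r}")
    emissions = np.asarray(hmm.match_emissions, dtype=float)
    # node 0 is the non-emitting begin state
    columns = emissions[1:]
    columns = columns / columns.sum(axis=1, keepdims=True)
    background = np.asarray(pyhmmer.plan7.Background(hmm.alphabet).residue_frequencies, dtype=float)
    n_seqs = int(hmm.nseq) if hmm.nseq is not None else 1
    hmm_name = hmm.name or "profile"
    if isinstance(hmm_name, bytes):
        hmm_name = hmm_name.decode()
    return ProfileModel(columns, background, n_seqs, name=hmm_name)


def _read_profile_table(path: Path) -> ProfileModel:
    name, n_seqs, background, columns = "profile", 1, None, []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("# profile"):
            for token in line.split()[2:]:
                key, _, value = token.partition("=")
                if key == "name":
                    name = value
                elif key == "n_seqs":
                    n_seqs = int(value)
        elif line.startswith("# background"):
            background = np.array([float(v) for v in line.split()[2:]], dtype=float)
        elif line.startswith("#"):
            continue
        else:
            values = np.array([float(v) for v in line.split()], dtype=float)
            if values.shape != (20,):
                raise ParseError(f"{path}:{lineno}: expected 20 emission values, got {len(values)}")
            columns.append(values)
    if not columns:
        raise ParseError(f"{path}: no profile columns found")
    if background is None:
        background = uniform_background()
    return ProfileModel(np.array(columns), background, n_seqs, name=name)


def write_profile(profile: ProfileModel, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# profile name={profile.name} n_seqs={profile.n_seqs_source}\n")
        fh.write("# background " + " ".join(f"{v:.9g}" for v in profile.background) + "\n")
        for col in profile.columns:
            fh.write("\t".join(f"{v:.9g}" for v in col) + "\n")


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def write_graphml(graph, path: PathLike) -> None:
    """Write a networkx graph as GraphML."""
    import networkx as nx

    nx.write_graphml(graph, str(path))
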