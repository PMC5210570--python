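"""Profile-profile comparison in bits, profile construction from alignments.

A profile is a list of per-column emission distributions over the 20 amino
acids.  Two profiles are compared by local (Smith-Waterman) dynamic
programming with affine gaps over the column-pair log-odds

    s(i, j) = log2( sum_a p_i(a) * q_j(a) / bg(a) )

— the dot product of the two emission vectors weighted against the
background, in bits.  A column pair that co-emits like the background scores
0; identical point-mass columns under a uniform background score
``log2(20) ~ 4.32`` bits each.  The score is symmetric and non-negative.

This keeps the bit scale of profile-comparison tools (so a 10-bit network
edge threshold retains its meaning) while replacing the full HMM co-emission
algebra with a fully specified column dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AMINO_ACIDS, GAP, MSA, ProfileModel, uniform_background

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ProfileScore:
    """Best local path score in bits plus its coordinates (0-based, inclusive)."""

    score: float
    path_start: tuple[int, int] | None = None
    path_end: tuple[int, int] | None = None


def build_profile(
    msa: MSA,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str | None = None,
) -> ProfileModel:
    """Estimate match-state emissions from an alignment.

    Per column, over the ungapped rows: ``emission_a = (count_a + pseudocount
    * bg_a) / (n_ungapped + pseudocount)``.  Columns that are gaps in more
    than half of the rows are treated as insert columns and dropped.
    Unknown residues ('X') count as gaps.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    columns = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        residues = [c for c in col if c in AA_INDEX]
        gap_fraction = 1.0 - len(residues) / len(col)
        if gap_fraction > 0.5:
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[AA_INDEX[c]] += 1
        columns.append((counts + pseudocount * bg) / (len(residues) + pseudocount))
    if not columns:
        raise ValueError("no match columns: every column is majority-gap")
    return ProfileModel(
        np.array(columns), bg, n_seqs_source=msa.n_rows, name=name or "profile"
    )


def sequence_profile(
    seq: str, pseudocount: float = 1.0, background: np.ndarray | None = None, name: str | None = None
) -> ProfileModel:
    """Single-sequence profile (point masses smoothed by the pseudocount)."""
    return build_profile(MSA([(name or "seq", seq)]), pseudocount, background, name=name)


def _log_odds_cells(p: ProfileModel, q: ProfileModel) -> np.ndarray:
    # averaging the two backgrounds keeps the score symmetric in its arguments
    bg = 0.5 * (p.background + q.background)
    if np.any(bg <= 0):
        raise ValueError("background contains a zero entry")
    weighted = p.columns / bg[None, :]  # (Lp, 20)
    return np.log2(weighted @ q.columns.T)


def compare_profiles(
    p: ProfileModel,
    q: ProfileModel,
    gap_open: float = 3.0,
    gap_extend: float = 0.3,
) -> ProfileScore:
    """Best local alignment of two profiles, in bits (Gotoh affine gaps).

    ``gap_open`` is the cost of the first gapped column, ``gap_extend`` of
    each further one, both in bits.  The score of the empty alignment is 0,
    so the result is never negative.
    """
    cells = _log_odds_cells(p, q)
    m, n = cells.shape
    h = np.zeros((m + 1, n + 1))
    e = np.full((m + 1, n + 1), -np.inf)  # gap in p (horizontal)
    f = np.full((m + 1, n + 1), -np.inf)  # gap in q (vertical)
    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        hi, hprev = h[i], h[i - 1]
        ei, fi, fprev = e[i], f[i], f[i - 1]
        row_cells = cells[i - 1]
        for j in range(1, n + 1):
            ei[j] = max(hi[j - 1] - gap_open, ei[j - 1] - gap_extend)
            fi[j] = max(hprev[j] - gap_open, fprev[j] - gap_extend)
            score = max(0.0, hprev[j - 1] + row_cells[j - 1], ei[j], fi[j])
            hi[j] = score
            if score > best:
                best, best_cell = score, (i - 1, j - 1)
    if best_cell is None:
        return ProfileScore(0.0)
    start = _traceback_start(h, e, f, cells, gap_open, gap_extend, best_cell)
    return ProfileScore(float(best), start, best_cell)


def _traceback_start(h, e, f, cells, gap_open, gap_extend, end) -> tuple[int, int]:
    i, j = end[0] + 1, end[1] + 1
    state = "h"
    while h[i, j] > 0 if state == "h" else True:
        if state == "h":
            if h[i, j] == h[i - 1, j - 1] + cells[i - 1, j - 1]:
                i, j = i - 1, j - 1
                if h[i, j] == 0:
                    break
            elif h[i, j] == e[i, j]:
                state = "e"
            elif h[i, j] == f[i, j]:
                state = "f"
            else:  # local start
                break
        elif state == "e":
            if e[i, j] == h[i, j - 1] - gap_open:
                state = "h"
            j -= 1
        else:
            if f[i, j] == h[i - 1, j] - gap_open:
                state = "h"
            i -= 1
    return (i, j)
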