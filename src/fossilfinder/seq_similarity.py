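"""Local sequence similarity between lost-gene loci and candidate transcripts.

Provides an affine-gap Smith-Waterman aligner (vectorized over
anti-diagonals), a translated (3x3 forward frame) protein-level search,
shuffle-based empirical significance, the random-GLCP empirical FDR screen,
and IUPAC consensus motif matching.

Gap costs are positive magnitudes: a gap of length k costs
``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -(10**9)

_NUC_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"
_AA_CODES = {aa: i for i, aa in enumerate(_AA_ALPHABET)}

STOP_SCORE = -10

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


@dataclass
class LocalAlignment:
    """Best-scoring local alignment between two sequences."""

    score: int
    q_interval: tuple[int, int]  # half-open interval in seq_a
    t_interval: tuple[int, int]  # half-open interval in seq_b
    length: int  # alignment columns
    identity: float
    significance: float | None = None
    frame_a: int | None = None
    frame_b: int | None = None


def encode_dna(seq: str) -> np.ndarray:
    try:
        return np.array([_NUC_CODES[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r}") from exc


def nucleotide_matrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int64)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N scores as mismatch, even against N
    m[:, 4] = mismatch
    return m


def protein_matrix(name: str = "BLOSUM62", stop_score: int = STOP_SCORE) -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load(name)
    m = np.zeros((len(_AA_ALPHABET), len(_AA_ALPHABET)), dtype=np.int64)
    for a, i in _AA_CODES.items():
        for b, j in _AA_CODES.items():
            if a == "*" or b == "*":
                m[i, j] = stop_score
            else:
                try:
                    m[i, j] = int(blosum[a, b])
                except (KeyError, IndexError):
                    m[i, j] = 0
    return m


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_CODES.get(c, _AA_CODES["X"]) for c in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# Smith-Waterman core (Gotoh affine gaps, anti-diagonal vectorization)
# ---------------------------------------------------------------------------

def _sw_score_only(a: np.ndarray, b: np.ndarray, submat: np.ndarray,
                   gap_open: int, gap_extend: int) -> int:
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    Hm1 = np.zeros(n, dtype=np.int64)
    Hm2 = np.zeros(n, dtype=np.int64)
    Em1 = np.full(n, NEG, dtype=np.int64)
    Fm1 = np.full(n, NEG, dtype=np.int64)
    best = 0
    for d in range(n + m - 1):
        lo, hi = max(0, d - m + 1), min(n - 1, d)
        idx = np.arange(lo, hi + 1)
        j = d - idx
        shifted = np.maximum(idx - 1, 0)
        diag = np.where((idx > 0) & (j > 0), Hm2[shifted], 0) + submat[a[idx], b[j]]
        E = np.where(j > 0, np.maximum(Hm1[idx] - gap_open, Em1[idx] - gap_extend), NEG)
        F = np.where(idx > 0,
                     np.maximum(Hm1[shifted] - gap_open, Fm1[shifted] - gap_extend), NEG)
        H = np.maximum(np.maximum(diag, 0), np.maximum(E, F))
        hmax = int(H.max())
        if hmax > best:
            best = hmax
        Hm2 = Hm1
        Hm1 = np.zeros(n, dtype=np.int64)
        Hm1[idx] = H
        Em1 = np.full(n, NEG, dtype=np.int64)
        Em1[idx] = E
        Fm1 = np.full(n, NEG, dtype=np.int64)
        Fm1[idx] = F
    return best


def _sw_full(a: np.ndarray, b: np.ndarray, submat: np.ndarray,
             gap_open: int, gap_extend: int) -> LocalAlignment:
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0.0)
    H = np.zeros((n, m), dtype=np.int64)
    E = np.full((n, m), NEG, dtype=np.int64)
    F = np.full((n, m), NEG, dtype=np.int64)
    for d in range(n + m - 1):
        lo, hi = max(0, d - m + 1), min(n - 1, d)
        idx = np.arange(lo, hi + 1)
        j = d - idx
        shifted = np.maximum(idx - 1, 0)
        diag = np.where(
            (idx > 0) & (j > 0), H[shifted, np.maximum(j - 1, 0)], 0
        ) + submat[a[idx], b[j]]
        Ed = np.where(
            j > 0,
            np.maximum(H[idx, np.maximum(j - 1, 0)] - gap_open,
                       E[idx, np.maximum(j - 1, 0)] - gap_extend),
            NEG,
        )
        Fd = np.where(
            idx > 0,
            np.maximum(H[shifted, j] - gap_open, F[shifted, j] - gap_extend),
            NEG,
        )
        E[idx, j] = Ed
        F[idx, j] = Fd
        H[idx, j] = np.maximum(np.maximum(diag, 0), np.maximum(Ed, Fd))

    flat = int(np.argmax(H))
    i, j = divmod(flat, m)
    score = int(H[i, j])
    if score == 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0.0)

    end_a, end_b = i + 1, j + 1
    a_lo, b_lo = i, j
    cols = ident = 0
    state = "H"
    while i >= 0 and j >= 0:
        if state == "H":
            h = H[i, j]
            if h <= 0:
                break
            d_src = (H[i - 1, j - 1] if i > 0 and j > 0 else 0) + submat[a[i], b[j]]
            if h == d_src:
                cols += 1
                ident += int(a[i] == b[j])
                a_lo, b_lo = i, j
                i -= 1
                j -= 1
                continue
            if h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":
            cols += 1
            b_lo = j
            if j > 0 and E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # state == "F"
            cols += 1
            a_lo = i
            if i > 0 and F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return LocalAlignment(
        score=score,
        q_interval=(a_lo, end_a),
        t_interval=(b_lo, end_b),
        length=cols,
        identity=ident / cols if cols else 0.0,
    )


def smith_waterman(
    seq_a: str,
    seq_b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
    traceback: bool = True,
) -> LocalAlignment:
    """Optimal local nucleotide alignment under affine gap costs.

    Plus strand only; N scores as a mismatch against everything.
    """
    a, b = encode_dna(seq_a), encode_dna(seq_b)
    submat = nucleotide_matrix(match, mismatch)
    if traceback:
        return _sw_full(a, b, submat, gap_open, gap_extend)
    score = _sw_score_only(a, b, submat, gap_open, gap_extend)
    return LocalAlignment(score, (0, 0), (0, 0), 0, 0.0)


def smith_waterman_score(seq_a: str, seq_b: str, match: int = 1, mismatch: int = -2,
                         gap_open: int = 5, gap_extend: int = 2) -> int:
    return _sw_score_only(
        encode_dna(seq_a), encode_dna(seq_b), nucleotide_matrix(match, mismatch),
        gap_open, gap_extend,
    )


def translate_frames(seq: str) -> list[str]:
    """Peptides of the three forward reading frames (standard genetic code)."""
    from Bio.Seq import Seq

    out = []
    for f in range(3):
        sub = seq[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if len(sub) >= 3 else "")
    return out


def translated_similarity(
    seq_a: str,
    seq_b: str,
    substitution_table: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    traceback: bool = True,
) -> LocalAlignment:
    """Best local peptide alignment over the 3x3 forward frame pairs.

    Stop codons score ``STOP_SCORE`` against everything.  Intervals are in
    peptide coordinates of the winning frames.
    """
    if len(seq_a) < 3 or len(seq_b) < 3:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0.0)
    submat = protein_matrix(substitution_table)
    frames_a = translate_frames(seq_a)
    frames_b = translate_frames(seq_b)
    best: LocalAlignment | None = None
    for fa, pa in enumerate(frames_a):
        ca = encode_protein(pa)
        for fb, pb in enumerate(frames_b):
            cb = encode_protein(pb)
            if traceback:
                aln = _sw_full(ca, cb, submat, gap_open, gap_extend)
            else:
                aln = LocalAlignment(
                    _sw_score_only(ca, cb, submat, gap_open, gap_extend),
                    (0, 0), (0, 0), 0, 0.0,
                )
            aln.frame_a, aln.frame_b = fa, fb
            if best is None or aln.score > best.score:
                best = aln
    return best


def empirical_significance(
    alignment_score: int,
    seq_a: str,
    seq_b: str,
    n_shuffles: int = 200,
    seed: int = 0,
    score_fn=None,
    **scoring,
) -> float:
    """Shuffle-based p-value: mononucleotide shuffles of seq_b re-scored vs seq_a.

    p = (#{score(shuffled) >= score} + 1) / (n_shuffles + 1).
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    if score_fn is None:
        a = encode_dna(seq_a)
        submat = nucleotide_matrix(scoring.get("match", 1), scoring.get("mismatch", -2))
        go, ge = scoring.get("gap_open", 5), scoring.get("gap_extend", 2)
        b = encode_dna(seq_b)
        hits = 0
        for _ in range(n_shuffles):
            shuf = rng.permutation(b)
            if _sw_score_only(a, shuf, submat, go, ge) >= alignment_score:
                hits += 1
        return (hits + 1) / (n_shuffles + 1)
    letters = list(seq_b)
    hits = 0
    for _ in range(n_shuffles):
        shuf = "".join(np.array(letters)[rng.permutation(len(letters))])
        if score_fn(seq_a, shuf) >= alignment_score:
            hits += 1
    return (hits + 1) / (n_shuffles + 1)


# ---------------------------------------------------------------------------
# random-GLCP empirical FDR
# ---------------------------------------------------------------------------

def pairwise_similarity_fdr(
    real_pairs: list[tuple[str, str]],
    sequences: dict[str, str],
    glcp_pool: list[str],
    thresholds: list[float],
    k: int = 10,
    n_shuffles: int = 100,
    seed: int = 0,
    **scoring,
) -> dict:
    """Empirical FDR of the sequence-similarity screen via random GLCP decoys.

    For each real (GLCP, candidate) pair, ``k`` random GLCPs (excluding the
    pair's own) are aligned to the candidate with identical parameters.
    FDR(t) = (average number of random pairs significant at t) /
    (number of real pairs significant at t); NA where no real pair is
    significant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)

    def pair_p(sa: str, sb: str, sub_seed: int) -> float:
        score = smith_waterman_score(sa, sb, **scoring)
        return empirical_significance(score, sa, sb, n_shuffles, sub_seed, **scoring)

    real_p: list[float] = []
    random_p: list[list[float]] = []
    for glcp, cand in real_pairs:
        real_p.append(pair_p(sequences[glcp], sequences[cand], int(rng.integers(2**31))))
        pool = sorted(set(glcp_pool) - {glcp})
        draws = rng.choice(pool, size=min(k, len(pool)), replace=False)
        random_p.append(
            [pair_p(sequences[g], sequences[cand], int(rng.integers(2**31))) for g in draws]
        )

    fdr: dict[float, float] = {}
    for t in thresholds:
        n_real = sum(1 for p in real_p if p <= t)
        avg_random = sum(
            sum(1 for p in ps if p <= t) / len(ps) for ps in random_p if ps
        )
        fdr[t] = avg_random / n_real if n_real else float("nan")
    return {"fdr": fdr, "real_p": real_p, "random_p": random_p}


# ---------------------------------------------------------------------------
# motif matching
# ---------------------------------------------------------------------------

def motif_match(consensus_iupac: str, sequence_window: str) -> int:
    """Ungapped position-wise IUPAC comparison from position 1.

    Returns the number of positions where the window base is in the consensus
    code's allowed set.
    """
    if len(sequence_window) < len(consensus_iupac):
        raise ValueError("window shorter than consensus")
    count = 0
    for code, base in zip(consensus_iupac.upper(), sequence_window.upper()):
        if code not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC consensus character {code!r}")
        if base not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC sequence character {base!r}")
        if base in IUPAC_SETS[code]:
            count += 1
    return count


TISU_CONSENSUS = "SAASATGGCGGC"
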