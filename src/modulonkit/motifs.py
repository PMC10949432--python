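"""PSSM construction from aligned binding sites and max-window motif scoring.

The position-specific scoring matrix stores per-position base probabilities
(counts plus a pseudocount, normalised) and log-odds scores in bits:
log2(probability / background). The background comes from the mononucleotide
frequencies of a caller-supplied sequence set — binding sites, promoters, or
genome — or from explicit frequencies; it is a required argument because the
choice materially changes the scores. Scanning slides the matrix over every
window at step 1 (both strands by default) and reports the best-scoring
window, ties broken toward the smallest offset with the forward strand
first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pssm", "build_pssm", "motif_search", "score_operon_promoters"]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class Pssm:
    """Log-odds motif model (bits) with its probability matrix and background."""

    probabilities: np.ndarray  # width x 4 (A, C, G, T)
    background: np.ndarray  # length-4
    log_odds: np.ndarray  # width x 4, log base 2
    pseudocount: float

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probabilities.argmax(axis=1))

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "alphabet": BASES,
            "probabilities": self.probabilities.tolist(),
            "background": self.background.tolist(),
            "log_odds": self.log_odds.tolist(),
            "pseudocount": self.pseudocount,
        }


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        codes[arr == ord(base)] = i
    return codes


def base_frequencies(sequences: list[str]) -> np.ndarray:
    """Mononucleotide frequencies over a sequence set (non-ACGT ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = _encode(seq)
        codes = codes[codes >= 0]
        counts += np.bincount(codes, minlength=4)
    if counts.sum() == 0:
        raise ValueError("background sequences contain no ACGT bases")
    return counts / counts.sum()


def build_pssm(
    aligned_sites: list[str],
    background_source: list[str] | dict[str, float] | np.ndarray,
    pseudocount: float = 0.5,
) -> Pssm:
    """Build a log-odds PSSM from equal-length aligned binding sites.

    Per-position base counts get ``pseudocount`` added before normalisation
    (column sums include 4x the pseudocount). ``background_source`` is
    either a set of sequences whose mononucleotide frequencies define the
    background, or explicit frequencies (dict keyed by base, or length-4
    array in A,C,G,T order). Observed bases with zero background frequency
    are an error. Scores are in bits.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError("aligned sites must all have the same length")
    for s in aligned_sites:
        if any(c not in _BASE_INDEX for c in s.upper()):
            raise ValueError(f"site {s!r} contains non-ACGT characters")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    counts = np.zeros((width, 4))
    for s in aligned_sites:
        codes = _encode(s)
        counts[np.arange(width), codes] += 1.0
    probs = (counts + pseudocount) / (len(aligned_sites) + 4 * pseudocount)

    if isinstance(background_source, dict):
        bg = np.array([background_source[b] for b in BASES], dtype=float)
    elif isinstance(background_source, np.ndarray):
        bg = np.asarray(background_source, dtype=float)
    else:
        bg = base_frequencies(list(background_source))
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must be length-4 and sum to 1")
    observed = counts.sum(axis=0) > 0
    if np.any(observed & (bg == 0)):
        raise ValueError("zero background frequency for an observed base")

    with np.errstate(divide="ignore"):
        log_odds = np.log2(np.where(probs > 0, probs, np.nan) / np.where(bg > 0, bg, np.nan))
    log_odds = np.where(np.isnan(log_odds), -np.inf, log_odds)
    return Pssm(probabilities=probs, background=bg, log_odds=log_odds, pseudocount=pseudocount)


def _scan_strand(codes: np.ndarray, log_odds: np.ndarray, on_invalid: str) -> np.ndarray:
    """Score every width-w window at step 1; invalid windows get -inf."""
    w = log_odds.shape[0]
    n_win = codes.size - w + 1
    scores = np.full(n_win, -np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.all() and on_invalid == "error":
        raise ValueError("sequence contains non-ACGT characters")
    if valid.any():
        vw = windows[valid]
        scores[valid] = log_odds[np.arange(w), vw].sum(axis=1)
    return scores


def motif_search(
    sequence: str,
    pssm: Pssm,
    scan_reverse_complement: bool = True,
    on_invalid: str = "skip",
) -> tuple[float, int, str]:
    """Best-scoring window of the PSSM over a sequence.

    Returns (best score in bits, 0-based offset on the given sequence,
    strand '+'/'-'). On the reverse strand the offset refers to the
    window's position in forward coordinates. Ties break toward the
    smallest offset, forward strand first. Windows containing non-ACGT
    characters are skipped (or raise, per ``on_invalid``).
    """
    if len(sequence) < pssm.width:
        raise ValueError(
            f"sequence length {len(sequence)} < motif width {pssm.width}"
        )
    codes = _encode(sequence)
    fwd = _scan_strand(codes, pssm.log_odds, on_invalid)
    # smallest offset among windows tied with the maximum (1e-9 tolerance:
    # windows with permuted score multisets round differently)
    best_score = float(fwd.max())
    best_offset = int(np.flatnonzero(fwd >= best_score - 1e-9)[0])
    strand = "+"
    if scan_reverse_complement:
        rc_codes = _encode(sequence.upper().translate(_COMPLEMENT)[::-1])
        rev = _scan_strand(rc_codes, pssm.log_odds, on_invalid)
        # rc-window offset j maps to forward offset n - w - j; reversing the
        # score array indexes it by forward offset directly
        rev_fwd = rev[::-1]
        # forward strand wins ties; 1e-9 guards against summation-order
        # rounding when the two strands score identically
        if rev_fwd.max() > best_score + 1e-9:
            best_score = float(rev_fwd.max())
            best_offset = int(np.flatnonzero(rev_fwd >= best_score - 1e-9)[0])
            strand = "-"
    if not np.isfinite(best_score):
        raise ValueError("no valid window (all windows contain non-ACGT characters)")
    return best_score, best_offset, strand


def score_operon_promoters(
    operon_map,
    promoters: dict[str, str],
    pssm: Pssm,
    scan_reverse_complement: bool = True,
) -> pd.DataFrame:
    """Best motif score per operon, inherited by member genes.

    ``promoters`` maps an operon's lead gene (or the operon id itself) to
    its upstream sequence. Operons without a promoter are flagged and
    excluded from downstream modeling. Returns one row per operon plus a
    ``gene_scores`` frame in ``.attrs`` mapping every member gene to its
    operon's score.
    """
    rows = []
    gene_rows = []
    for op_id, members in operon_map.operons.items():
        lead = members[0]
        seq = promoters.get(lead, promoters.get(op_id))
        if seq is None:
            warnings.warn(f"operon {op_id!r} has no promoter; excluded", stacklevel=2)
            rows.append(
                {"operon_id": op_id, "lead_gene": lead, "best_score": np.nan,
                 "best_offset": -1, "strand_scanned": "none", "has_promoter": False}
            )
            continue
        score, offset, strand = motif_search(
            seq, pssm, scan_reverse_complement=scan_reverse_complement
        )
        rows.append(
            {"operon_id": op_id, "lead_gene": lead, "best_score": score,
             "best_offset": offset, "strand_scanned": strand, "has_promoter": True}
        )
        for g in members:
            gene_rows.append({"gene_id": g, "operon_id": op_id, "best_score": score})
    table = pd.DataFrame(rows)
    table.attrs["gene_scores"] = pd.DataFrame(gene_rows)
    return table
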