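"""FIMO-style PWM scanning with exact p-values.

Scores are log-odds in bits against a 0-order background.  P-values come
from the exact null distribution of the window score, computed by dynamic
programming over the discretized score grid: the score of a random window is
the sum of independent per-position scores, so its probability mass function
is the convolution of the per-column mass functions under the background.

Both the reported window score and its p-value live on the discretized grid
(default granularity 1e-3 bits), so the p-value is exact for the score that
accompanies it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .ppr_code import PWM

_ENC = np.full(256, 4, dtype=np.int8)  # 4 = ambiguous
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class Background:
    """0-order base composition over A,C,G,T."""

    freq: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ScanError("background must be 4 positive frequencies summing to 1")
        object.__setattr__(self, "freq", f)


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-position per-base log-odds scores (bits) plus their integer grid.

    ``iscores[j, b] = round(scores[j, b] / granularity)``; window p-values are
    computed on the integer grid so DP and enumeration agree exactly.
    """

    scores: np.ndarray  # (L, 4) bits
    granularity: float = 1e-3
    pwm_pseudocount_weight: float = 0.01

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if not np.isfinite(s).all():
            raise ScanError("score matrix has non-finite entries")
        if self.granularity <= 0:
            raise ScanError("granularity must be > 0")
        object.__setattr__(self, "scores", s)

    @property
    def iscores(self) -> np.ndarray:
        return np.rint(self.scores / self.granularity).astype(np.int64)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the window score on the integer grid."""

    support: np.ndarray  # integer grid units, ascending
    pmf: np.ndarray
    granularity: float

    def __post_init__(self) -> None:
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ScanError("pmf does not sum to 1")

    @property
    def cumulative_upper(self) -> np.ndarray:
        """P(score >= s) for each support point."""
        return self.pmf[::-1].cumsum()[::-1]


@dataclass(frozen=True)
class Hit:
    seq_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    matched_sequence: str  # genome-forward orientation
    score: float  # bits, on the discretized grid
    pvalue: float


def estimate_background(sequence: str, pseudocount: float = 1.0) -> Background:
    """0-order background from a sequence; non-ACGT symbols are ignored."""
    codes = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    if counts.sum() == 0:
        raise ScanError("no valid ACGT bases in sequence")
    freq = (counts + pseudocount) / (counts.sum() + 4 * pseudocount)
    if (freq == 0).any():
        raise ScanError("zero background frequency; use a positive pseudocount")
    return Background(freq=freq, pseudocount=pseudocount)


def log_odds(
    pwm: PWM,
    bg: Background,
    pwm_pseudo: float = 0.01,
    granularity: float = 1e-3,
) -> ScoreMatrix:
    """Log-odds scores with PWM probabilities floored by background mixing.

    p̃(b) = (1 − pwm_pseudo)·p(b) + pwm_pseudo·bg(b);  score = log2(p̃/bg).
    The PWM's U column scores against T in the scanned DNA.
    """
    probs = pwm.probs
    if pwm_pseudo == 0 and (probs == 0).any():
        raise ScanError("infinite score: zero probability with pwm_pseudo=0")
    floored = (1.0 - pwm_pseudo) * probs + pwm_pseudo * bg.freq[None, :]
    return ScoreMatrix(
        scores=np.log2(floored / bg.freq[None, :]),
        granularity=granularity,
        pwm_pseudocount_weight=pwm_pseudo,
    )


def score_window(sm: ScoreMatrix, window: str) -> float:
    """Raw (undiscretized) score of one window; N scores the column minimum."""
    if len(window) != len(sm):
        raise ScanError(
            f"window length {len(window)} != matrix length {len(sm)}"
        )
    codes = _ENC[np.frombuffer(window.upper().encode("ascii"), dtype=np.uint8)]
    ext = np.hstack([sm.scores, sm.scores.min(axis=1, keepdims=True)])
    return float(ext[np.arange(len(sm)), codes].sum())


def score_distribution(sm: ScoreMatrix, bg: Background) -> ScoreDistribution:
    """Exact pmf of the window score under the background, by convolution."""
    iscores = sm.iscores
    lo = int(iscores.min(axis=1).sum())
    hi = int(iscores.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # running offset: current pmf index 0 corresponds to grid value `origin`
    origin = 0
    cur = np.array([1.0])
    for j in range(len(sm)):
        col = iscores[j]
        cmin = int(col.min())
        new = np.zeros(len(cur) + int(col.max()) - cmin)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift : shift + len(cur)] += bg.freq[b] * cur
        cur = new
        origin += cmin
    pmf[origin - lo : origin - lo + len(cur)] = cur
    return ScoreDistribution(
        support=np.arange(lo, hi + 1), pmf=pmf, granularity=sm.granularity
    )


def pvalue(dist: ScoreDistribution, s: float) -> float:
    """P(score >= s) under the null; ``s`` in bits, snapped down to the grid."""
    k = int(np.floor(s / dist.granularity + 1e-9))
    if k <= dist.support[0]:
        return 1.0
    if k > dist.support[-1]:
        return 0.0
    idx = k - int(dist.support[0])
    return float(dist.cumulative_upper[idx])


def _pvalue_grid(dist: ScoreDistribution, k: np.ndarray) -> np.ndarray:
    """Vectorised P(score >= k) for integer grid scores k."""
    cu = dist.cumulative_upper
    lo, hi = int(dist.support[0]), int(dist.support[-1])
    idx = np.clip(k - lo, 0, hi - lo)
    out = cu[idx]
    out[k <= lo] = 1.0
    out[k > hi] = 0.0
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _window_iscores(iscores: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Integer grid score of every window, N scoring the column minimum."""
    L = iscores.shape[0]
    ext = np.hstack([iscores, iscores.min(axis=1, keepdims=True)])  # (L, 5)
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n, L)
    return ext[np.arange(L)[None, :], windows].sum(axis=1)


def scan(
    genome: Iterable[tuple[str, str]] | str | Path,
    pwm: PWM,
    *,
    pvalue_threshold: float = 1e-3,
    top_k: int | None = 10,
    both_strands: bool = True,
    circular: bool = False,
    pwm_pseudo: float = 0.01,
    granularity: float = 1e-3,
    background: Background | None = None,
) -> list[Hit]:
    """Scan genome records on both strands and return top hits by p-value.

    ``genome`` is a FASTA path or an iterable of ``(seq_id, sequence)``.  The
    background defaults to the 0-order composition of the scanned sequence
    itself.  In circular mode the first PWM-length−1 bases are appended so
    origin-spanning sites are scored; reported starts stay in the original
    coordinate range.  Ties are broken by (seq_id, start, strand +<−);
    ``top_k=None`` keeps every hit under the threshold.
    """
    if isinstance(genome, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(genome), "fasta")]
    else:
        records = [(sid, str(seq)) for sid, seq in genome]
    if not records:
        raise ScanError("empty genome")

    if background is None:
        # estimate from both strands so scanning a reverse-complemented
        # genome yields mirrored hits with identical scores and p-values
        joined = "".join(seq for _, seq in records)
        background = estimate_background(joined + reverse_complement(joined))
    sm = log_odds(pwm, background, pwm_pseudo=pwm_pseudo, granularity=granularity)
    dist = score_distribution(sm, background)
    L = len(pwm)

    hits: list[Hit] = []
    for seq_id, seq in records:
        true_len = len(seq)
        if true_len < L:
            warnings.warn(
                f"record {seq_id} shorter than the PWM ({true_len} < {L}); skipped",
                stacklevel=2,
            )
            continue
        scan_seq = seq + seq[: L - 1] if circular else seq
        strands = ["+", "-"] if both_strands else ["+"]
        for strand in strands:
            s = scan_seq if strand == "+" else reverse_complement(scan_seq)
            codes = _ENC[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
            ks = _window_iscores(sm.iscores, codes)
            pvals = _pvalue_grid(dist, ks)
            for w in np.flatnonzero(pvals <= pvalue_threshold):
                if strand == "+":
                    start = int(w)
                else:
                    start = len(scan_seq) - int(w) - L
                if circular and start >= true_len:
                    continue  # same site as its unwrapped copy
                end = start + L
                matched = scan_seq[start:end]
                hits.append(
                    Hit(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        strand=strand,
                        matched_sequence=matched.upper(),
                        score=float(ks[w]) * granularity,
                        pvalue=float(pvals[w]),
                    )
                )
    hits.sort(key=lambda h: (h.pvalue, h.seq_id, h.start, h.strand))
    return hits[:top_k] if top_k is not None else hits


def write_hits_tsv(hits: Sequence[Hit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matched_sequence": h.matched_sequence,
                "score_bits": h.score,
                "pvalue": h.pvalue,
            }
            for h in hits
        ],
        columns=[
            "seq_id", "start", "end", "strand",
            "matched_sequence", "score_bits", "pvalue",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_hits_gff3(hits: Sequence[Hit], path: str | Path, source: str = "ppredit") -> None:
    """GFF3 output: 1-based inclusive coordinates, score = −log10 p-value."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, 1):
            score = -np.log10(h.pvalue) if h.pvalue > 0 else np.inf
            fh.write(
                f"{h.seq_id}\t{source}\tbinding_site\t{h.start + 1}\t{h.end}\t"
                f"{score:.4g}\t{h.strand}\t.\tID=hit{i};seq={h.matched_sequence}\n"
            )
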