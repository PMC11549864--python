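"""Linking reporter MRL to endogenous translation efficiency (TE).

TE of a native transcript is the log2 ratio of library-size-normalized
ribosome-profiling counts (ORFspM) over mRNA abundance (tpm).  Reporters
are matched to native 5'UTRs by glocal pairwise alignment (the 50-nt
reporter aligned end-to-end inside the longer native UTR) and the MRL/TE
relationship is summarized by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats


@dataclass(frozen=True)
class TranscriptCounts:
    transcript_id: str
    gene_id: str
    orfspm: float
    tpm: float
    utr5_sequence: str = ""

    def __post_init__(self):
        if self.orfspm < 0 or self.tpm < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TEResult:
    transcript_id: str
    log2_te: float


def compute_te(records: Iterable[TranscriptCounts]) -> list[TEResult]:
    """log2(ORFspM/tpm) per gene after the standard filters.

    Keeps records with ORFspM > 1 and tpm > 1 (strictly above), then within
    each gene keeps the single record with the highest ORFspM (ties go to
    the first transcript_id in lexicographic order).
    """
    kept = [r for r in records if r.orfspm > 1 and r.tpm > 1]
    by_gene: dict[str, TranscriptCounts] = {}
    for r in sorted(kept, key=lambda r: r.transcript_id):
        best = by_gene.get(r.gene_id)
        if best is None or r.orfspm > best.orfspm:
            by_gene[r.gene_id] = r
    chosen = sorted(by_gene.values(), key=lambda r: r.transcript_id)
    return [TEResult(r.transcript_id, float(np.log2(r.orfspm / r.tpm))) for r in chosen]


def _make_aligner(match: float = 1.0, mismatch: float = 0.0,
                  gap_open: float = -1.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps for the native flanks: glocal alignment of the short
    # reporter within the longer native UTR
    try:
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.88 naming
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class ReporterMatch:
    reporter_index: int
    transcript_id: str
    identity: float
    score: float


def match_reporters_to_native(
    reporter_seqs: Sequence[str],
    natives: Sequence[TranscriptCounts],
    min_identity: float = 0.9,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> list[ReporterMatch]:
    """Best-scoring native 5'UTR per reporter, filtered by identity.

    Identity is the number of identical aligned columns divided by the
    reporter length; ties on score go to the first transcript_id.
    """
    aligner = aligner or _make_aligner()
    matches = []
    natives_sorted = sorted(natives, key=lambda r: r.transcript_id)
    for i, rep in enumerate(reporter_seqs):
        best: Optional[ReporterMatch] = None
        for native in natives_sorted:
            if not native.utr5_sequence:
                continue
            aln = aligner.align(native.utr5_sequence, rep)[0]
            identities = aln.counts().identities
            identity = identities / len(rep)
            if identity < min_identity:
                continue
            if best is None or aln.score > best.score:
                best = ReporterMatch(i, native.transcript_id, identity, aln.score)
        if best is not None:
            matches.append(best)
    return matches


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation with input validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlate_mrl_te(
    reporter_seqs: Sequence[str],
    reporter_mrl: Sequence[float],
    natives: Sequence[TranscriptCounts],
    min_identity: float = 0.9,
) -> tuple[pd.DataFrame, float]:
    """Full pipeline: TE per gene, reporter matching, Pearson correlation.

    Returns the matched-pairs table (reporter_index, transcript_id, mrl,
    log2_te, identity) and the correlation coefficient.
    """
    te = {r.transcript_id: r.log2_te for r in compute_te(natives)}
    usable = [n for n in natives if n.transcript_id in te]
    matches = match_reporters_to_native(reporter_seqs, usable, min_identity)
    rows = [
        {"reporter_index": m.reporter_index, "transcript_id": m.transcript_id,
         "mrl": float(reporter_mrl[m.reporter_index]),
         "log2_te": te[m.transcript_id], "identity": m.identity}
        for m in matches
    ]
    pairs = pd.DataFrame(rows)
    r = pearson_r(pairs["mrl"], pairs["log2_te"]) if len(pairs) >= 3 else float("nan")
    return pairs, r
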