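"""Upstream translation-signal detection and classification for 5'UTR reporters.

A 5'UTR may contain AUG codons (uAUGs) that recruit scanning ribosomes before
they reach the main ORF's translation initiation site (TIS).  The functional
consequence depends on the reading frame of the uAUG relative to the coding
sequence and on whether an in-frame stop codon occurs before the TIS:

* ``IF_UORF``  — complete upstream ORF (uAUG + in-UTR stop), in frame with the CDS
* ``OOF_UORF`` — complete upstream ORF, out of frame with the CDS
* ``NTE``      — in-frame uAUG without an in-UTR stop: translation produces an
  N-terminally extended protein
* ``OUORF``    — out-of-frame uAUG without an in-UTR stop: an overlapping uORF
  running into the CDS
* ``CONTROL``  — no uAUG at all
* ``EXCLUDED`` — two or more uAUGs (ambiguous upstream translation signal)

Coordinates are 0-based on the UTR string; the TIS-relative position of index
``p`` in a length-``L`` UTR is ``p - L`` (so index 47 of a 50-mer is -3).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simdata import ReporterLibrary

VALID_BASES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TGA", "TAG"})


class UpstreamClass(str, enum.Enum):
    """Functional class of the upstream translation signal of a 5'UTR."""

    CONTROL = "CONTROL"
    IF_UORF = "IF_UORF"
    OOF_UORF = "OOF_UORF"
    OUORF = "OUORF"
    NTE = "NTE"
    EXCLUDED = "EXCLUDED"


#: Classes assignable to a single-uAUG sequence (everything but CONTROL/EXCLUDED).
SINGLE_UAUG_CLASSES = (
    UpstreamClass.IF_UORF,
    UpstreamClass.OOF_UORF,
    UpstreamClass.OUORF,
    UpstreamClass.NTE,
)


@dataclass(frozen=True)
class UpstreamAnnotation:
    """Classification result for one 5'UTR sequence."""

    class_call: UpstreamClass
    uaug_positions: tuple[int, ...]
    primary_uaug: Optional[int] = None
    stop_start: Optional[int] = None
    frame_offset: Optional[int] = None


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")


def find_uaugs(sequence: str) -> list[int]:
    """Return all 0-based start indices of ATG codons fully inside the UTR.

    Overlapping occurrences are all reported (e.g. ``"ATGATG..."`` yields
    ``[0, 3]``; ``"ATATGTG"`` yields ``[2]``).
    """
    _check_alphabet(sequence)
    hits = []
    start = sequence.find("ATG")
    while start != -1:
        hits.append(start)
        start = sequence.find("ATG", start + 1)
    return hits


def _scan_for_stop(sequence: str, uaug: int) -> Optional[int]:
    """First in-frame stop codon fully within the UTR downstream of ``uaug``."""
    L = len(sequence)
    for q in range(uaug + 3, L - 2, 3):
        if sequence[q : q + 3] in STOP_CODONS:
            return q
    return None


def classify_upstream(sequence: str) -> UpstreamAnnotation:
    """Classify the upstream translation signal of a 5'UTR.

    Zero uAUGs gives CONTROL; two or more give EXCLUDED.  For exactly one
    uAUG at index ``p``, codons ``p, p+3, ...`` are scanned while the full
    codon lies within the UTR (a codon straddling the UTR/CDS boundary does
    not count).  A stop found in the UTR makes a complete uORF (IF vs OOF by
    whether ``(L - p) % 3 == 0``); no stop makes an NTE (in frame) or an
    overlapping uORF (out of frame).
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    uaugs = find_uaugs(sequence)
    if not uaugs:
        return UpstreamAnnotation(UpstreamClass.CONTROL, ())
    if len(uaugs) >= 2:
        return UpstreamAnnotation(UpstreamClass.EXCLUDED, tuple(uaugs))
    p = uaugs[0]
    L = len(sequence)
    frame = (L - p) % 3
    stop = _scan_for_stop(sequence, p)
    if stop is not None:
        call = UpstreamClass.IF_UORF if frame == 0 else UpstreamClass.OOF_UORF
    else:
        call = UpstreamClass.NTE if frame == 0 else UpstreamClass.OUORF
    return UpstreamAnnotation(call, (p,), primary_uaug=p, stop_start=stop, frame_offset=frame)


def classify_single_uaug(sequence: str, p: int) -> UpstreamClass:
    """Class a uAUG at index ``p`` would have if it were the only one.

    Used by the simulator to assign an additive effect to each uAUG of a
    multi-uAUG (EXCLUDED) sequence.
    """
    L = len(sequence)
    frame = (L - p) % 3
    if _scan_for_stop(sequence, p) is not None:
        return UpstreamClass.IF_UORF if frame == 0 else UpstreamClass.OOF_UORF
    return UpstreamClass.NTE if frame == 0 else UpstreamClass.OUORF


def kozak_minus3(sequence: str) -> str:
    """Base at TIS-relative position -3 (the strongest Kozak-context position)."""
    if len(sequence) < 3:
        raise ValueError("sequence shorter than 3 nt")
    return sequence[len(sequence) - 3]


def gc_fraction(sequence: str) -> float:
    """Fraction of G/C bases."""
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def composition_stats(library: "ReporterLibrary") -> dict:
    """Per-library composition summary.

    Returns a dict with:

    * ``per_reporter`` — DataFrame: gc_fraction, n_uaug, class per reporter
    * ``class_frequencies`` — Series over classes, summing to 1
    * ``uaug_position_histogram`` — Series indexed by TIS-relative position,
      counting uAUG occurrences over all reporters
    """
    seqs = list(library.sequences)
    if not seqs:
        raise ValueError("empty library")
    gc = np.array([gc_fraction(s) for s in seqs])
    uaugs = [find_uaugs(s) for s in seqs]
    classes = [classify_upstream(s).class_call.value for s in seqs]
    per_reporter = pd.DataFrame(
        {"gc_fraction": gc, "n_uaug": [len(u) for u in uaugs], "class": classes}
    )
    freqs = per_reporter["class"].value_counts(normalize=True).reindex(
        [c.value for c in UpstreamClass], fill_value=0.0
    )
    positions = [p - len(s) for s, us in zip(seqs, uaugs) for p in us]
    hist = pd.Series(positions, dtype=int).value_counts().sort_index()
    hist.index.name = "tis_relative_position"
    return {
        "per_reporter": per_reporter,
        "class_frequencies": freqs,
        "uaug_position_histogram": hist,
    }


def filter_library(
    library: "ReporterLibrary", drop_uaug: bool = False, drop_ug_prefix: bool = False
) -> "ReporterLibrary":
    """Remove reporters matching occlusion filters, preserving order and splits.

    ``drop_uaug`` removes every reporter containing at least one uAUG;
    ``drop_ug_prefix`` removes reporters whose UTR starts with the dinucleotide
    UG (DNA spelling ``"TG"``) — an adapter-context artifact filter.
    """
    frame = library.frame
    keep = np.ones(len(frame), dtype=bool)
    if drop_uaug:
        keep &= np.array(["ATG" not in s for s in frame["sequence"]])
    if drop_ug_prefix:
        keep &= np.array([not s.startswith("TG") for s in frame["sequence"]])
    applied = []
    if drop_uaug:
        applied.append("-uAUG")
    if drop_ug_prefix:
        applied.append("-UG")
    out = library.subset(keep)
    if applied:
        out.provenance = (library.provenance + " " + " ".join(applied)).strip()
    return out


def annotation_table(library: "ReporterLibrary") -> pd.DataFrame:
    """Annotation export: one row per reporter with TIS-relative coordinates."""
    rows = []
    for i, s in enumerate(library.sequences):
        ann = classify_upstream(s)
        L = len(s)
        rows.append(
            {
                "sequence_id": f"{library.kind}:{i}",
                "class": ann.class_call.value,
                "uaug_position": ann.primary_uaug - L if ann.primary_uaug is not None else pd.NA,
                "stop_position": ann.stop_start - L if ann.stop_start is not None else pd.NA,
                "frame_offset": ann.frame_offset if ann.frame_offset is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)
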