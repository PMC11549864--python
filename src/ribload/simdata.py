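"""Synthetic MPRA reporter libraries with a planted, rule-based MRL function.

Polysome-profiling MPRAs measure a mean ribosome load (MRL, ribosomes per
mRNA) for each member of a library of fixed-length 5'UTR reporters.  This
module simulates such libraries so that the modeling, attribution and
occlusion machinery can be exercised end to end with known ground truth.

The planted MRL rule encodes the regulatory features such assays recover:
a favorable Kozak context (A/G at TIS-relative -3) raises MRL; upstream
AUGs/uORFs lower it in a class- and position-dependent way, most strongly
for uORFs starting in a window upstream of the TIS; GC content imposes a
structure-like penalty.  Observation noise is Gaussian on the MRL and read
counts are Poisson.  MRL is simulated directly rather than via polysome
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .utr_features import (
    UpstreamClass,
    classify_single_uaug,
    classify_upstream,
    find_uaugs,
    gc_fraction,
    kozak_minus3,
)

BASES = np.array(list("ACGT"))

DEFAULT_CLASS_EFFECTS: dict[UpstreamClass, float] = {
    UpstreamClass.IF_UORF: -1.5,
    UpstreamClass.OOF_UORF: -2.5,
    UpstreamClass.OUORF: -2.5,
    UpstreamClass.NTE: +0.2,
    UpstreamClass.CONTROL: 0.0,
}


@dataclass
class SimParams:
    """Parameters of the planted MRL ground-truth function.

    Units: MRL terms are in ribosomes/mRNA.  ``pos_window`` is in
    TIS-relative coordinates (index ``p`` of a length-``L`` UTR maps to
    ``p - L``); uAUGs starting inside it carry their full class effect,
    those outside are attenuated by ``pos_decay``.
    """

    base_mrl: float = 5.0
    kozak_bonus: float = 0.8
    effect_by_class: dict[UpstreamClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    pos_window: tuple[int, int] = (-47, -32)
    pos_decay: float = 0.5
    gc_coef: float = 2.0
    noise_sd: float = 0.3
    read_count_mean: float = 200.0
    excluded_floor: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.pos_decay <= 1):
            raise ValueError("pos_decay must be in (0, 1]")
        if self.read_count_mean <= 0:
            raise ValueError("read_count_mean must be positive")
        missing = [
            c
            for c in (
                UpstreamClass.IF_UORF,
                UpstreamClass.OOF_UORF,
                UpstreamClass.OUORF,
                UpstreamClass.NTE,
                UpstreamClass.CONTROL,
            )
            if c not in self.effect_by_class
        ]
        if missing:
            raise ValueError(f"effect_by_class missing entries: {missing}")


@dataclass
class Reporter:
    """One 50-nt 5'UTR reporter."""

    sequence: str
    mrl: Optional[float] = None
    total_reads: Optional[int] = None
    library_id: str = ""


class ReporterLibrary:
    """Ordered collection of reporters backed by a DataFrame.

    Columns: ``sequence`` (str), ``total_reads`` (nullable int), ``mrl``
    (float, NaN until simulated/measured), ``split`` (train/test/validation
    or NA).
    """

    COLUMNS = ("sequence", "total_reads", "mrl", "split")

    def __init__(self, frame: pd.DataFrame, kind: str = "random", provenance: str = ""):
        frame = frame.reset_index(drop=True).copy()
        for col in self.COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan if col in ("total_reads", "mrl") else pd.NA
        if frame["mrl"].dtype == object:
            frame["mrl"] = pd.to_numeric(frame["mrl"])
        self.frame = frame[list(self.COLUMNS)]
        self.kind = kind
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sequences(self) -> np.ndarray:
        return self.frame["sequence"].to_numpy()

    @property
    def mrl(self) -> np.ndarray:
        return self.frame["mrl"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "ReporterLibrary":
        return ReporterLibrary(self.frame.loc[np.asarray(mask)], self.kind, self.provenance)

    def subset_split(self, label: str) -> "ReporterLibrary":
        return self.subset((self.frame["split"] == label).to_numpy())

    def split_sizes(self) -> dict[str, int]:
        return self.frame["split"].value_counts(dropna=True).to_dict()

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], kind: str = "random", provenance: str = ""
    ) -> "ReporterLibrary":
        return cls(pd.DataFrame({"sequence": list(sequences)}), kind, provenance)


def _draw_sequences(rng: np.random.Generator, n: int, length: int, probs: np.ndarray) -> list[str]:
    if n == 0:
        return []
    idx = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in BASES[idx]]


def generate_random_library(
    n: int,
    length: int = 50,
    base_probs: Iterable[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> ReporterLibrary:
    """i.i.d. per-position random reporter library (the "random" MPRA design)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    probs = np.asarray(list(base_probs), dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("base_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    seqs = _draw_sequences(rng, n, length, probs)
    return ReporterLibrary.from_sequences(
        seqs, kind="random", provenance=f"generate_random_library(n={n}, seed={seed})"
    )


def generate_humanlike_library(
    n: int,
    length: int = 50,
    gc_target: float = 0.6,
    uaug_keep_prob: float = 0.3,
    seed: int = 0,
) -> ReporterLibrary:
    """Human-like reporter library: elevated GC, depleted uAUGs.

    Positions are drawn with total G/C probability ``gc_target`` (split
    evenly between G and C, likewise A/T).  Sequences containing at least
    one uAUG are kept with probability ``uaug_keep_prob``; rejected draws
    are resampled until ``n`` sequences are accepted.
    """
    if not (0 < gc_target < 1):
        raise ValueError("gc_target must be in (0, 1)")
    if not (0 <= uaug_keep_prob <= 1):
        raise ValueError("uaug_keep_prob must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    probs = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    while len(accepted) < n:
        batch = _draw_sequences(rng, max(n - len(accepted), 256), length, probs)
        for s in batch:
            if "ATG" in s and rng.random() >= uaug_keep_prob:
                continue
            accepted.append(s)
            if len(accepted) == n:
                break
    return ReporterLibrary.from_sequences(
        accepted,
        kind="humanlike",
        provenance=(
            f"generate_humanlike_library(n={n}, gc_target={gc_target}, "
            f"uaug_keep_prob={uaug_keep_prob}, seed={seed})"
        ),
    )


def _position_weight(p: int, length: int, params: SimParams) -> float:
    rel = p - length
    lo, hi = params.pos_window
    return 1.0 if lo <= rel <= hi else params.pos_decay


def true_mrl(sequence: str, params: SimParams) -> float:
    """Noise-free planted MRL of a reporter.

    ``base_mrl + kozak_bonus·1[−3 ∈ {A,G}] + upstream_effect − gc_coef·GC``
    where the upstream effect is the class effect of the single uAUG scaled
    by its position weight; for multi-uAUG (EXCLUDED) sequences the
    per-uAUG effects (each classified as if alone) are summed and floored
    at ``excluded_floor``.
    """
    L = len(sequence)
    if L != 50:
        raise ValueError(f"expected a 50-nt sequence, got {L} nt")
    ann = classify_upstream(sequence)
    if ann.class_call == UpstreamClass.CONTROL:
        upstream = 0.0
    elif ann.class_call == UpstreamClass.EXCLUDED:
        total = sum(
            params.effect_by_class[classify_single_uaug(sequence, p)]
            * _position_weight(p, L, params)
            for p in ann.uaug_positions
        )
        upstream = max(total, params.excluded_floor)
    else:
        upstream = params.effect_by_class[ann.class_call] * _position_weight(
            ann.primary_uaug, L, params
        )
    kozak = params.kozak_bonus if kozak_minus3(sequence) in "AG" else 0.0
    return params.base_mrl + kozak + upstream - params.gc_coef * gc_fraction(sequence)


def simulate_library(library: ReporterLibrary, params: SimParams) -> ReporterLibrary:
    """Attach noisy MRL observations and Poisson read counts to a library."""
    rng = np.random.default_rng(params.seed)
    truths = np.array([true_mrl(s, params) for s in library.sequences])
    noise = rng.normal(0.0, params.noise_sd, size=len(truths)) if params.noise_sd > 0 else 0.0
    reads = rng.poisson(params.read_count_mean, size=len(truths))
    frame = library.frame.copy()
    frame["mrl"] = truths + noise
    frame["total_reads"] = reads
    out = ReporterLibrary(frame, library.kind, library.provenance)
    out.provenance = (out.provenance + f" simulate_library(seed={params.seed})").strip()
    return out


def assign_random_split(
    library: ReporterLibrary, n_test: int, seed: int = 0
) -> ReporterLibrary:
    """Random train/test partition (the random-library design has no read
    based split; test membership is drawn uniformly)."""
    if not (0 <= n_test <= len(library)):
        raise ValueError("n_test out of range")
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(len(library), size=n_test, replace=False)
    split = np.full(len(library), "train", dtype=object)
    split[test_idx] = "test"
    frame = library.frame.copy()
    frame["split"] = split
    return ReporterLibrary(frame, library.kind, library.provenance)


def with_params(params: SimParams, **overrides) -> SimParams:
    """Copy of ``params`` with fields replaced (convenience for configs)."""
    return replace(params, **overrides)
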