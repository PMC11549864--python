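"""Reading/writing reporter libraries (TSV, FASTA), read-count splits, and
run configuration.

The canonical tabular dialect is tab-delimited UTF-8 with a header and '.'
decimals; FASTA output wraps at 60 columns with record ids
``<library_id>:<index>``.  Readers canonicalize sequences to uppercase DNA
(U→T) and drop records that are not exactly 50 nt, logging the count;
structurally malformed rows are itemized and rejected rather than guessed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import ReporterLibrary
from .utr_features import VALID_BASES

logger = logging.getLogger("ribload")

REQUIRED_COLUMNS = ("sequence", "total_reads", "mrl")
REPORTER_LENGTH = 50


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the field."""


def canonicalize_sequence(raw: str) -> str:
    """Uppercase DNA form: RNA U becomes T; anything else must be A/C/G/T."""
    seq = str(raw).strip().upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)!r}")
    return seq


def write_library(path: Union[str, Path], library: ReporterLibrary) -> None:
    library.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_fasta(path: Union[str, Path], library: ReporterLibrary) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{library.kind}:{i}", description="")
        for i, s in enumerate(library.sequences)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_library(path: Union[str, Path], kind: str = "external",
                 expected_length: int = REPORTER_LENGTH) -> ReporterLibrary:
    """Load a library from TSV (sequence, total_reads, mrl[, split]) or FASTA.

    Records whose canonical sequence is not ``expected_length`` nt are
    dropped (with a logged count); rows with invalid characters raise with
    an itemized message.
    """
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        frame = pd.DataFrame({"sequence": seqs})
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
    bad_rows = []
    canon = []
    for i, raw in enumerate(frame["sequence"]):
        try:
            canon.append(canonicalize_sequence(raw))
        except ValueError as exc:
            bad_rows.append(f"row {i}: {exc}")
            canon.append(None)
    if bad_rows:
        raise ValueError("unparsable rows:\n" + "\n".join(bad_rows))
    frame["sequence"] = canon
    lengths = frame["sequence"].str.len()
    keep = lengths == expected_length
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d records with length != %d", n_dropped, expected_length)
    return ReporterLibrary(frame.loc[keep], kind=kind, provenance=str(path))


def split_by_reads(library: ReporterLibrary, n_test: int) -> ReporterLibrary:
    """Read-count split: the ``n_test`` reporters with most reads are the
    test set, the remainder the training set (ties broken by stored order)."""
    if n_test >= len(library):
        raise ValueError(f"n_test={n_test} must be smaller than library size {len(library)}")
    reads = library.frame["total_reads"].to_numpy(dtype=float)
    if np.isnan(reads).any():
        raise ValueError("total_reads missing; cannot split by reads")
    order = np.argsort(-reads, kind="stable")
    split = np.full(len(library), "train", dtype=object)
    split[order[:n_test]] = "test"
    frame = library.frame.copy()
    frame["split"] = split
    out = ReporterLibrary(frame, library.kind, library.provenance)
    out.provenance = (out.provenance + f" split_by_reads(n_test={n_test})").strip()
    return out


# -- run configuration ---------------------------------------------------

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "seed": None,  # mandatory
    "simdata": {
        "n_random": 20000, "n_humanlike": 10000, "length": 50,
        "gc_target": 0.6, "uaug_keep_prob": 0.3,
        "base_mrl": 5.0, "kozak_bonus": 0.8, "gc_coef": 2.0,
        "pos_decay": 0.5, "noise_sd": 0.3, "read_count_mean": 200.0,
        "n_test": 4000,
    },
    "model": {
        "epochs": 3, "filters_per_layer": 120, "kernel_size": 8,
        "dense_units": 40, "dropout_rate": 0.2, "learning_rate": 1e-3,
        "batch_size": 128,
    },
    "attribution": {"steps": 50, "fraction": 0.1, "max_maps": 500},
    "occlusion": {"attribution_sample": 200, "steps": 20},
    "transfer": {"epoch_min": 1, "epoch_max": 15},
    "te": {"min_identity": 0.9},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Union[str, Path, None] = None,
                overrides: Optional[dict] = None) -> dict:
    """Load + validate a YAML run configuration (defaults merged in)."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if cfg.get("seed") is None:
        raise ConfigError("seed: a seed is mandatory in the config")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: must be an integer")
    sim = cfg["simdata"]
    for key in ("n_random", "n_humanlike"):
        if sim[key] < 0:
            raise ConfigError(f"simdata.{key}: must be >= 0")
    if not (0 < sim["gc_target"] < 1):
        raise ConfigError("simdata.gc_target: must be in (0, 1)")
    if not (0 <= sim["uaug_keep_prob"] <= 1):
        raise ConfigError("simdata.uaug_keep_prob: must be in [0, 1]")
    if sim["noise_sd"] < 0:
        raise ConfigError("simdata.noise_sd: must be >= 0")
    if cfg["model"]["epochs"] < 1:
        raise ConfigError("model.epochs: must be >= 1")
    if cfg["mode"] not in ("synthetic", "real-data"):
        raise ConfigError("mode: must be 'synthetic' or 'real-data'")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
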