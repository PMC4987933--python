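"""Affinity index parsing and the refined-minus-core benchmark protocol.

A benchmark index is a whitespace-delimited text file, one complex per
line: PDB code, resolution, deposition year, the affinity as
-log10(Kd|Ki) in molar, and the raw affinity string (e.g. ``Kd=50uM``).
Training uses complexes of the refined set that are not in the core set;
the core set is the blind test.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "AffinityKind",
    "AffinityRecord",
    "ParsedAffinity",
    "SplitSpec",
    "IndexParseError",
    "affinity_to_plog",
    "format_affinity",
    "parse_index",
    "split_train_test",
    "make_folds",
]


class AffinityKind(str, enum.Enum):
    Kd = "Kd"
    Ki = "Ki"
    IC50 = "IC50"


class IndexParseError(ValueError):
    pass


_UNIT_TO_MOLAR = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12, "fM": 1e-15,
}

_AFFINITY_RE = re.compile(
    r"^(Kd|Ki|IC50)\s*([=<>~])\s*([0-9.]+(?:[eE][+-]?\d+)?)\s*(fM|pM|nM|uM|mM|M)$"
)


class ParsedAffinity(NamedTuple):
    p_affinity: float
    kind: AffinityKind
    qualifier: str  # '=', '<', '>' or '~'


@dataclass(frozen=True)
class AffinityRecord:
    """One labelled complex of the benchmark index."""

    pdb_code: str
    resolution: float
    year: int
    p_affinity: float
    affinity_kind: AffinityKind
    raw_string: str
    qualifier: str = "="

    def __post_init__(self):
        if not math.isfinite(self.p_affinity):
            raise ValueError("p_affinity must be finite")


@dataclass
class SplitSpec:
    """Disjoint train/test id sets, optionally with CV folds over train."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]] | None = None
    seed: int = 0

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        if self.folds is not None:
            flat = [i for f in self.folds for i in f]
            if sorted(flat) != sorted(self.train_ids):
                raise ValueError("folds must partition the training ids exactly")


def affinity_to_plog(raw: str) -> ParsedAffinity:
    """Convert ``Kd=50uM``-style strings to pAffinity = -log10(molar).

    Qualifiers '<', '>' and '~' are preserved as metadata (censored
    labels; excluded from training by default).
    """
    m = _AFFINITY_RE.match(raw.strip())
    if m is None:
        raise ValueError(f"unparseable affinity string: {raw!r}")
    kind, qual, value, unit = m.groups()
    v = float(value)
    if v <= 0:
        raise ValueError(f"non-positive affinity value in {raw!r}")
    molar = v * _UNIT_TO_MOLAR[unit]
    return ParsedAffinity(-math.log10(molar), AffinityKind(kind), qual)


def format_affinity(p_affinity: float, kind: AffinityKind = AffinityKind.Kd) -> str:
    """Inverse of :func:`affinity_to_plog`: render pAffinity as a Kd/Ki string."""
    return f"{kind.value}={10.0 ** (-p_affinity):.6e}M"


def parse_index(
    index_text: str,
    allow_ic50: bool = False,
    allow_censored: bool = False,
) -> list[AffinityRecord]:
    """Parse a benchmark-style affinity index.

    Lines starting with '#' are comments.  Data lines carry at least five
    whitespace-separated columns: code, resolution, year, -logKd/Ki,
    affinity string.  The printed -log column is authoritative; it is
    cross-checked against the affinity string and a discrepancy above
    0.02 log units raises a data-quality warning.  IC50 entries are
    skipped by default (the refined-set rule admits only Ki and Kd), as
    are censored ('<', '>', '~') labels.
    """
    records: list[AffinityRecord] = []
    n_ic50 = n_censored = 0
    for lineno, line in enumerate(index_text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) < 5:
            raise IndexParseError(
                f"line {lineno}: expected >= 5 columns, got {len(cols)}"
            )
        code = cols[0].lower()
        try:
            resolution = float(cols[1])
            year = int(cols[2])
            printed_p = float(cols[3])
        except ValueError as exc:
            raise IndexParseError(f"line {lineno}: {exc}") from exc
        raw = cols[4]
        try:
            parsed = affinity_to_plog(raw)
        except ValueError as exc:
            raise IndexParseError(f"line {lineno}: {exc}") from exc
        if parsed.kind is AffinityKind.IC50 and not allow_ic50:
            n_ic50 += 1
            continue
        if parsed.qualifier != "=" and not allow_censored:
            n_censored += 1
            continue
        if abs(parsed.p_affinity - printed_p) > 0.02:
            warnings.warn(
                f"line {lineno} ({code}): printed -log value {printed_p:.3f} "
                f"disagrees with affinity string {raw!r} "
                f"({parsed.p_affinity:.3f})",
                stacklevel=2,
            )
        records.append(
            AffinityRecord(
                pdb_code=code,
                resolution=resolution,
                year=year,
                p_affinity=printed_p,
                affinity_kind=parsed.kind,
                raw_string=raw,
                qualifier=parsed.qualifier,
            )
        )
    if n_ic50:
        warnings.warn(f"skipped {n_ic50} IC50 entries", stacklevel=2)
    if n_censored:
        warnings.warn(f"skipped {n_censored} censored (<,>,~) entries", stacklevel=2)
    return records


def split_train_test(
    records: list[AffinityRecord], core_ids, seed: int = 0
) -> SplitSpec:
    """Refined-minus-core protocol: train = refined \\ core, test = core.

    Core ids absent from the records are warned about and excluded from
    the test set.
    """
    refined = [r.pdb_code for r in records]
    refined_set = set(refined)
    core = [c.lower() for c in core_ids]
    missing = [c for c in core if c not in refined_set]
    if missing:
        warnings.warn(
            f"{len(missing)} core ids absent from the index: {missing[:5]}...",
            stacklevel=2,
        )
    core_set = set(core) & refined_set
    train = [c for c in refined if c not in core_set]
    test = [c for c in refined if c in core_set]
    if not train or not test:
        raise ValueError(
            f"degenerate split: {len(train)} train / {len(test)} test complexes"
        )
    return SplitSpec(train_ids=train, test_ids=test, seed=seed)


def make_folds(train_ids, k: int, seed: int = 0) -> list[list[str]]:
    """Seeded shuffle + round-robin partition into k folds (sizes differ <= 1)."""
    ids = list(train_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds number of training ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        folds[pos % k].append(ids[idx])
    return folds
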