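"""Six-criterion ADME/drug-likeness compound screen and Tanimoto drug-likeness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .tables_io import HERB_CODES, CompoundRecord


@dataclass(frozen=True)
class ScreeningCriteria:
    """Inclusive thresholds for the six-descriptor compound screen."""

    mw_max: float = 500.0
    alogp_max: float = 5.0
    hdon_max: int = 5
    hacc_max: int = 10
    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        for name in ("mw_max", "alogp_max", "hdon_max", "hacc_max", "ob_min", "dl_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.ob_min < 0:
            raise ValueError("ob_min must be non-negative")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError("dl_min must lie in [0, 1]")


@dataclass(frozen=True)
class ScreenResult:
    """Output of :func:`screen_compounds`."""

    kept: tuple[CompoundRecord, ...]
    per_herb_counts: dict[str, int]
    unique_molecule_count: int

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def tanimoto_dl(a: Sequence[float], b: Sequence[float]) -> float:
    """Tanimoto coefficient A.B / (|A|^2 + |B|^2 - A.B) of two descriptor vectors.

    Equals 1 iff the (nonzero) vectors are identical; may be negative for
    real-valued descriptors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("descriptor vectors must be one-dimensional")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("descriptor vectors must be finite")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise ValueError("undefined Tanimoto coefficient: zero denominator")
    return dot / denom


def dl_against_reference(
    query: Sequence[float],
    reference: Sequence[Sequence[float]],
    aggregate: Literal["mean", "max"] = "mean",
) -> float:
    """Aggregate Tanimoto similarity of ``query`` against a drug reference set."""
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    if aggregate not in ("mean", "max"):
        raise ValueError(f"unknown aggregate: {aggregate!r}")
    sims = [tanimoto_dl(query, r) for r in reference]
    return float(np.mean(sims)) if aggregate == "mean" else float(np.max(sims))


def passes_criteria(record: CompoundRecord, criteria: ScreeningCriteria | None = None) -> bool:
    """True iff the record satisfies all six inclusive thresholds."""
    c = criteria or ScreeningCriteria()
    return (
        record.mw <= c.mw_max
        and record.alogp <= c.alogp_max
        and record.hdon <= c.hdon_max
        and record.hacc <= c.hacc_max
        and record.ob >= c.ob_min
        and record.dl >= c.dl_min
    )


def screen_compounds(
    records: Sequence[CompoundRecord], criteria: ScreeningCriteria | None = None
) -> ScreenResult:
    """Apply the six-criterion screen, preserving input order.

    Returns the kept herb-compound entries, a per-herb tally covering all
    eight herb codes (zeros included), and the number of distinct molecule
    identifiers among the kept entries.
    """
    c = criteria or ScreeningCriteria()
    kept = tuple(r for r in records if passes_criteria(r, c))
    counts = {h: 0 for h in HERB_CODES}
    for r in kept:
        counts[r.herb] += 1
    unique = len({r.mol_id for r in kept})
    return ScreenResult(kept=kept, per_herb_counts=counts, unique_molecule_count=unique)
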