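"""Semiquantitative plaque histology and the 0-4 vulnerability score.

Carotid endarterectomy plaques are routinely graded on four characteristics:
macrophage content, collagen content, smooth-muscle-cell (SMC) content
(each scored semiquantitatively as ``no/minor`` vs ``moderate/heavy``) and
fat content (percent of plaque area).  Each characteristic contributes one
point when it takes its *vulnerable* level:

* macrophages ``moderate/heavy``  -> +1
* collagen    ``no/minor``        -> +1
* SMCs        ``no/minor``        -> +1
* fat fraction >= 10 %            -> +1

The sum ranges from 0 (most stable plaque) to 4 (most vulnerable plaque).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PlaqueHistoRecord",
    "vulnerability_score",
    "score_cohort",
    "STABLE_LEVEL",
    "VULNERABLE_LEVEL",
]

#: The two-level semiquantitative vocabulary.
STABLE_LEVEL = "no/minor"
VULNERABLE_LEVEL = "moderate/heavy"

_LEVELS = frozenset({STABLE_LEVEL, VULNERABLE_LEVEL})

# inclusive threshold: >= 10 % fat counts as vulnerable
FAT_THRESHOLD = 10.0


def _normalize_level(value: str, field: str) -> str:
    if not isinstance(value, str):
        raise ValueError(f"field {field!r} must be a category string, got {value!r}")
    norm = value.strip().lower()
    if norm not in _LEVELS:
        raise ValueError(
            f"field {field!r} must be one of {sorted(_LEVELS)}, got {value!r}"
        )
    return norm


@dataclass(frozen=True)
class PlaqueHistoRecord:
    """One plaque's semiquantitative histology.

    Parameters
    ----------
    macrophages, collagen, smc
        ``"no/minor"`` or ``"moderate/heavy"`` (case-insensitive).
    fat_fraction
        Fat content as a percentage in [0, 100].
    """

    macrophages: str
    collagen: str
    smc: str
    fat_fraction: float

    def __post_init__(self) -> None:
        for field in ("macrophages", "collagen", "smc"):
            value = getattr(self, field)
            if value is None:
                raise ValueError(f"missing field {field!r}")
            object.__setattr__(self, field, _normalize_level(value, field))
        fat = self.fat_fraction
        if fat is None or (isinstance(fat, float) and fat != fat):
            raise ValueError("missing field 'fat_fraction'")
        fat = float(fat)
        if not 0.0 <= fat <= 100.0:
            raise ValueError(f"fat_fraction must be in [0, 100], got {fat}")
        object.__setattr__(self, "fat_fraction", fat)


def vulnerability_score(record: PlaqueHistoRecord) -> int:
    """Sum the four binary vulnerability indicators of one plaque.

    Returns an integer in {0, 1, 2, 3, 4}; 0 is the most stable plaque and 4
    the most vulnerable.  The fat criterion is inclusive at 10 %.
    """
    return (
        int(record.macrophages == VULNERABLE_LEVEL)
        + int(record.collagen == STABLE_LEVEL)
        + int(record.smc == STABLE_LEVEL)
        + int(record.fat_fraction >= FAT_THRESHOLD)
    )


def score_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, int]]:
    """Score every plaque in a cohort table.

    Parameters
    ----------
    records
        DataFrame with columns ``macrophages``, ``collagen``, ``smc``,
        ``fat_fraction``.

    Returns
    -------
    scored : DataFrame
        Copy of the input with a ``vulnerability_score`` column appended.
    distribution : dict
        Count of plaques per score level (only levels present).
    """
    required = ["macrophages", "collagen", "smc", "fat_fraction"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    scores: list[int] = []
    for idx, row in records.iterrows():
        try:
            rec = PlaqueHistoRecord(
                macrophages=row["macrophages"],
                collagen=row["collagen"],
                smc=row["smc"],
                fat_fraction=row["fat_fraction"],
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        scores.append(vulnerability_score(rec))
    scored = records.copy()
    scored["vulnerability_score"] = scores
    distribution = dict(pd.Series(scores, dtype=int).value_counts().sort_index())
    return scored, {int(k): int(v) for k, v in distribution.items()}
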