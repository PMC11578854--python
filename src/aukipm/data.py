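"""In-memory containers for the three demographic data streams.

The streams are (1) sparse breeding-pair survey counts, (2) per-individual
encounter-count histories from capture-mark-recapture (counts per breeding
season, not binary detections), and (3) annual productivity records (burrows
monitored, chicks fledged).  All containers are aligned to a
:class:`~aukipm.demography.StudyDesign` by 0-based year index; calendar years
appear only at the file boundary (:mod:`aukipm.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import StudyDesign


@dataclass(frozen=True)
class SurveyCounts:
    """Breeding-pair counts for survey years only: ``year_index -> count``."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        clean = {int(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in clean.values()):
            raise ValueError("pair counts must be nonnegative")
        object.__setattr__(self, "counts", clean)

    def validate_against(self, design: StudyDesign) -> None:
        extra = set(self.counts) - set(design.survey_indices.tolist())
        if extra:
            raise ValueError(f"counts present for non-survey year indices {sorted(extra)}")

    @property
    def year_indices(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.counts[t] for t in sorted(self.counts)], dtype=np.int64)


@dataclass(frozen=True)
class ProductivityData:
    """Annual burrow-monitoring records: ``B_t`` burrows, ``J_t`` fledglings."""

    burrows: np.ndarray
    fledged: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.burrows, dtype=np.int64)
        j = np.asarray(self.fledged, dtype=np.int64)
        if b.shape != j.shape or b.ndim != 1:
            raise ValueError("burrows and fledged must be 1-D and the same length")
        if np.any(b < 0) or np.any(j < 0) or np.any(j > b):
            raise ValueError("need 0 <= fledged <= burrows in every year")
        object.__setattr__(self, "burrows", b)
        object.__setattr__(self, "fledged", j)

    @property
    def n_years(self) -> int:
        return self.burrows.size


CHICK_AGE = 1   #: age-class label recorded for birds marked as chicks
ADULT_AGE = 4   #: age-class label for birds marked as (4+) adults


@dataclass(frozen=True)
class EncounterData:
    """Encounter-count histories ``c_{i,t}`` with marking metadata.

    counts : (n, T) int array; ``counts[i, t]`` is the number of encounters of
        individual ``i`` in season ``t``; entries before ``mark_idx[i]`` are
        structurally zero.  The count at the marking occasion is >= 1.
    mark_idx : (n,) 0-based year index of first capture.
    age_at_mark : (n,) either ``CHICK_AGE`` (marked as a nestling in its hatch
        year) or ``ADULT_AGE`` (marked as a 4+ adult; unknown-age adults are
        pooled into 4+).

    Age advances one class per season, capped at 4+.  A bird marked as a chick
    in season ``m`` is a hatch-year bird at ``m`` and in age class
    ``min(t - m, 4)`` at season ``t``; first-year survival applies to the
    ``m -> m+1`` transition only.
    """

    counts: np.ndarray
    mark_idx: np.ndarray
    age_at_mark: np.ndarray
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        mark = np.asarray(self.mark_idx, dtype=int)
        age = np.asarray(self.age_at_mark, dtype=int)
        if counts.ndim != 2:
            raise ValueError("counts must be (n_individuals, n_years)")
        n, T = counts.shape
        if mark.shape != (n,) or age.shape != (n,):
            raise ValueError("mark_idx and age_at_mark must have one entry per individual")
        if np.any(counts < 0):
            raise ValueError("encounter counts must be nonnegative")
        if np.any((mark < 0) | (mark >= T)):
            raise ValueError("mark_idx outside the study frame")
        if np.any(counts[np.arange(n), mark] < 1):
            raise ValueError("the count at the marking occasion must be >= 1")
        rows, cols = np.nonzero(counts)
        if np.any(cols < mark[rows]):
            raise ValueError("nonzero counts before the marking occasion")
        if not np.all(np.isin(age, (CHICK_AGE, ADULT_AGE))):
            raise ValueError(f"age_at_mark must be {CHICK_AGE} (chick) or {ADULT_AGE} (adult)")
        ids = tuple(self.ids) if self.ids else tuple(f"ind{i:06d}" for i in range(n))
        if len(ids) != n:
            raise ValueError("ids must have one entry per individual")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "mark_idx", mark)
        object.__setattr__(self, "age_at_mark", age)
        object.__setattr__(self, "ids", ids)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    @property
    def is_chick(self) -> np.ndarray:
        return self.age_at_mark == CHICK_AGE

    def collapse(self) -> tuple["EncounterData", np.ndarray]:
        """Group identical (history, marking) records.

        Returns a deduplicated :class:`EncounterData` and the multiplicity of
        each unique record.  Likelihoods are additive over individuals, so a
        weighted sum over unique records is exact; with sparse re-encounters
        (most chicks are never seen again) this shrinks the data considerably.
        """
        key = np.concatenate(
            [self.counts, self.mark_idx[:, None], self.age_at_mark[:, None]], axis=1)
        uniq, inverse, mult = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        n_u = uniq.shape[0]
        first = np.full(n_u, -1, dtype=int)
        seen_first = {}
        for i, g in enumerate(inverse):
            if g not in seen_first:
                seen_first[g] = i
        first = np.array([seen_first[g] for g in range(n_u)], dtype=int)
        dedup = EncounterData(
            counts=uniq[:, :-2],
            mark_idx=uniq[:, -2],
            age_at_mark=uniq[:, -1],
            ids=tuple(self.ids[i] for i in first),
        )
        return dedup, mult.astype(np.int64)

    # -- tabular round trip ------------------------------------------------
    def to_frame(self, design: StudyDesign) -> pd.DataFrame:
        """Long format: one row per individual-season from marking onward."""
        recs = []
        for i in range(self.n_individuals):
            m = self.mark_idx[i]
            for t in range(m, self.n_years):
                recs.append((self.ids[i], design.years[t], int(self.age_at_mark[i]),
                             design.years[m], int(self.counts[i, t])))
        return pd.DataFrame(recs, columns=["individual_id", "year", "age_at_mark",
                                           "mark_year", "encounter_count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: StudyDesign) -> "EncounterData":
        required = {"individual_id", "year", "age_at_mark", "mark_year", "encounter_count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"encounter table is missing columns {sorted(missing)}")
        dup = frame.duplicated(subset=["individual_id", "year"])
        if dup.any():
            rows = (frame.index[dup] + 2).tolist()  # 1-based + header
            raise ValueError(f"duplicate (individual_id, year) rows at lines {rows}")
        ids = list(dict.fromkeys(frame["individual_id"]))
        idx = {v: i for i, v in enumerate(ids)}
        T = design.n_years
        counts = np.zeros((len(ids), T), dtype=np.int64)
        mark = np.full(len(ids), -1, dtype=int)
        age = np.zeros(len(ids), dtype=int)
        for row in frame.itertuples(index=False):
            i = idx[row.individual_id]
            t = design.year_index(row.year)
            counts[i, t] = int(row.encounter_count)
            mark[i] = design.year_index(row.mark_year)
            age[i] = int(row.age_at_mark)
        return cls(counts=counts, mark_idx=mark, age_at_mark=age, ids=tuple(map(str, ids)))


@dataclass(frozen=True)
class DataBundle:
    """The three streams an integrated fit consumes (any may be None for the
    single-dataset fits)."""

    design: StudyDesign
    surveys: SurveyCounts | None = None
    encounters: EncounterData | None = None
    productivity: ProductivityData | None = None
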