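"""File formats, configuration and run plumbing.

All data and results travel as plain CSV keyed by calendar year (internal
0-based indices never leak into files); configuration and truth records are
YAML.  Schema validation is strict and failures name the offending rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import DataBundle, EncounterData, ProductivityData, SurveyCounts
from .demography import PopulationState, StudyDesign

__all__ = ["read_counts", "write_counts", "read_encounters", "write_encounters",
           "read_productivity", "write_productivity", "read_bundle",
           "write_scenario", "read_scenario", "extrapolate_pairs", "RunConfig",
           "write_draws", "write_summary"]

log = logging.getLogger("aukipm")

_COUNT_COLS = ["year", "pairs"]
_PROD_COLS = ["year", "burrows_monitored", "chicks_fledged"]


def _check_columns(frame: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = set(cols) - set(frame.columns)
    if missing:
        raise ValueError(f"{what} table is missing columns {sorted(missing)}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # 1-based data rows, +1 for the header line
    return (np.nonzero(mask.to_numpy())[0] + 2).tolist()


# ---------------------------------------------------------------------------
# survey counts
# ---------------------------------------------------------------------------

def read_counts(path, design: StudyDesign) -> SurveyCounts:
    """Read ``(year, pairs)`` survey counts; rows must be survey years."""
    frame = pd.read_csv(path)
    _check_columns(frame, _COUNT_COLS, "counts")
    bad = frame["pairs"] < 0
    if bad.any():
        raise ValueError(f"negative pair counts at lines {_bad_rows(bad)}")
    dup = frame.duplicated(subset="year")
    if dup.any():
        raise ValueError(f"duplicate survey years at lines {_bad_rows(dup)}")
    counts = {design.year_index(int(r.year)): int(r.pairs)
              for r in frame.itertuples(index=False)}
    sc = SurveyCounts(counts)
    sc.validate_against(design)
    return sc


def write_counts(path, counts: SurveyCounts, design: StudyDesign) -> None:
    years = [design.years[t] for t in sorted(counts.counts)]
    pd.DataFrame({"year": years, "pairs": counts.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# encounter histories (long format: the observation is a count, not a bit)
# ---------------------------------------------------------------------------

def read_encounters(path, design: StudyDesign) -> EncounterData:
    frame = pd.read_csv(path)
    bad = frame.get("encounter_count")
    if bad is not None and (bad < 0).any():
        raise ValueError(f"negative encounter counts at lines {_bad_rows(bad < 0)}")
    return EncounterData.from_frame(frame, design)


def write_encounters(path, enc: EncounterData, design: StudyDesign) -> None:
    enc.to_frame(design).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------

def read_productivity(path, design: StudyDesign) -> ProductivityData:
    frame = pd.read_csv(path)
    _check_columns(frame, _PROD_COLS, "productivity")
    bad = frame["chicks_fledged"] > frame["burrows_monitored"]
    if bad.any():
        raise ValueError(f"more fledglings than monitored burrows at lines {_bad_rows(bad)}")
    neg = (frame["chicks_fledged"] < 0) | (frame["burrows_monitored"] < 0)
    if neg.any():
        raise ValueError(f"negative productivity entries at lines {_bad_rows(neg)}")
    frame = frame.set_index("year").reindex(design.years)
    if frame.isna().any().any():
        missing = [y for y in design.years if y not in frame.dropna().index]
        raise ValueError(f"productivity rows missing for years {missing}")
    return ProductivityData(burrows=frame["burrows_monitored"].to_numpy(dtype=np.int64),
                            fledged=frame["chicks_fledged"].to_numpy(dtype=np.int64))


def write_productivity(path, prod: ProductivityData, design: StudyDesign) -> None:
    pd.DataFrame({"year": design.years, "burrows_monitored": prod.burrows,
                  "chicks_fledged": prod.fledged}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scenario directories
# ---------------------------------------------------------------------------

def _design_to_dict(design: StudyDesign) -> dict:
    return {"years": list(design.years), "survey_years": list(design.survey_years),
            "species_label": design.species_label}


def _design_from_dict(d: dict) -> StudyDesign:
    return StudyDesign(years=tuple(d["years"]), survey_years=tuple(d["survey_years"]),
                       species_label=d.get("species_label", "synthetic"))


def write_scenario(out_dir, config, bundle: DataBundle, states: PopulationState,
                   overwrite: bool = False) -> Path:
    """Write a self-describing scenario directory: three data CSVs, the truth
    record (config, true rates, latent trajectory) and the seed."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    design = bundle.design
    write_counts(out / "counts.csv", bundle.surveys, design)
    write_encounters(out / "cmr.csv", bundle.encounters, design)
    write_productivity(out / "productivity.csv", bundle.productivity, design)
    truth = {
        "design": _design_to_dict(design),
        "rng_seed": int(config.rng_seed),
        "initial_total_pairs": int(config.initial_total_pairs),
        "initial_immigrant_lambda": float(config.initial_immigrant_lambda),
        "chicks_marked_per_year": int(config.chicks_marked_per_year),
        "adults_marked_per_year": int(config.adults_marked_per_year),
        "burrows_per_year": int(config.burrows_per_year),
        "truth": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                  for k, v in config.truth.items()},
        "true_rates": {
            "alpha1": config.rates.alpha1.tolist(),
            "alpha2": config.rates.alpha2.tolist(),
            "f": config.rates.f.tolist(),
            "omega": float(config.rates.omega),
        },
        "true_detection": {
            "gamma1": config.detection.gamma1.tolist(),
            "gamma2": config.detection.gamma2.tolist(),
            "epsilon": config.detection.epsilon.tolist(),
            "theta": float(config.detection.theta),
        },
        "latent_states": {name: getattr(states, name).tolist()
                          for name in ("N1", "N2", "N3", "N4", "Nimm")},
        "package_version": __version__,
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    log.info("scenario written to %s (seed %d)", out, config.rng_seed)
    return out


def read_scenario(path) -> tuple[DataBundle, dict]:
    """Read a scenario directory back into a typed bundle plus truth record."""
    path = Path(path)
    with open(path / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    design = _design_from_dict(truth["design"])
    bundle = DataBundle(
        design=design,
        surveys=read_counts(path / "counts.csv", design),
        encounters=read_encounters(path / "cmr.csv", design),
        productivity=read_productivity(path / "productivity.csv", design),
    )
    return bundle, truth


def read_bundle(design: StudyDesign, counts_path=None, cmr_path=None,
                productivity_path=None) -> DataBundle:
    """Assemble a bundle from whichever stream files are given; omitted
    streams stay ``None`` so single-dataset fits work unchanged."""
    return DataBundle(
        design=design,
        surveys=read_counts(counts_path, design) if counts_path else None,
        encounters=read_encounters(cmr_path, design) if cmr_path else None,
        productivity=(read_productivity(productivity_path, design)
                      if productivity_path else None),
    )


# ---------------------------------------------------------------------------
# survey extrapolation helper
# ---------------------------------------------------------------------------

def extrapolate_pairs(occupied: int, n_quadrats: int, quadrat_area: float = 4.0,
                      breeding_area: float = 20_000.0) -> int:
    """Whole-colony breeding-pair estimate from quadrat occupancy.

    Occupied burrows per surveyed area (quadrat count x quadrat area, default
    2 m x 2 m) extrapolated to the colony's breeding habitat (default
    ~20,000 m^2), assuming evenly distributed burrows; rounded to an integer
    pair count.
    """
    if occupied < 0:
        raise ValueError("occupied burrow count must be nonnegative")
    if n_quadrats <= 0 or quadrat_area <= 0 or breeding_area <= 0:
        raise ValueError("areas and quadrat count must be positive")
    density = occupied / (n_quadrats * quadrat_area)
    return int(round(density * breeding_area))


# ---------------------------------------------------------------------------
# run configuration and result export
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one analysis run; a frozen copy (plus its
    hash and the package version) is written next to every output."""

    scenario_dir: str | None = None
    counts_path: str | None = None
    cmr_path: str | None = None
    productivity_path: str | None = None
    output_dir: str = "results"
    rng_seed: int = 0
    chains: int = 4
    draws: int = 1200
    burn: int = 300
    eps_year_effects: bool = False
    alpha1_mask_years: list[int] = field(default_factory=list)
    ltre_mode: str = "posterior_mean"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def freeze(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["config_hash"] = self.config_hash()
        payload["package_version"] = __version__
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def write_draws(path, draws, thin: int = 1) -> None:
    """Tabular CSV export of posterior draws (chain, draw, one column per
    scalar; annual series flattened as ``name[year]``)."""
    layout = draws.layout
    years = layout.spec.design.years
    cols = {}
    C, D = draws.n_chains, draws.n_draws
    idx = np.arange(0, D, thin)
    cols["chain"] = np.repeat(np.arange(C), idx.size)
    cols["draw"] = np.tile(idx, C)
    for name, arr in draws.samples.items():
        if name.startswith("_") or arr.shape[0] != C or arr.shape[1] != D:
            continue
        sub = arr[:, idx]
        if sub.ndim == 2:
            cols[name] = sub.reshape(-1)
        elif sub.ndim == 3:
            k = sub.shape[2]
            labels = years if k == len(years) else years[:k]
            for j in range(k):
                cols[f"{name}[{labels[j]}]"] = sub[:, :, j].reshape(-1)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_summary(path, summary: pd.DataFrame) -> None:
    summary.to_csv(path, index=False)
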