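"""Synthetic prescription-record generator.

Emulates the statistical structure of a one-year primary-care
dispensation register: a ~55/45 female/male split; three age strata
(0-21, 22-64, 65+) holding ~12/50/38% of patients but ~2/30/68% of
prescriptions; heavy-tailed drug popularity (a Zipf-like law, so a few
codes reach a large share of patients while many are prescribed to a
single patient); and non-random co-prescription planted as drug
*modules* — subsets of codes that patients assigned to the module draw
with boosted probability, creating a known positive φ-association
inside the module and none across modules.

All randomness flows from ``SimConfig.seed`` through a single
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field

import numpy as np

from .atc import ANATOMICAL_GROUPS, ATCCode, parse_atc
from .ingest import PrescriptionRecord

__all__ = ["ModuleSpec", "SimConfig", "generate_catalog", "generate_records", "records_to_csv"]

#: Observation window: one year of dispensations.
WINDOW_START = _dt.date(2018, 7, 1)
WINDOW_END = _dt.date(2019, 6, 30)

#: Age strata and the index year used to convert ages to birth years.
AGE_RANGES = ((0, 21), (22, 64), (65, 100))
INDEX_YEAR = 2019

# level-5 code space: letter x 2 digits x 2 letters x 2 digits
_MAX_CATALOG = 14 * 100 * 26 * 26 * 100


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-prescription module.

    Patients assigned to the module draw each prescription from the
    module's codes with probability ``boost`` (uniformly within the
    module) and from the global popularity law otherwise; ``share`` is
    the fraction of all patients assigned to the module.
    """

    codes: tuple[str, ...]
    boost: float
    share: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults reproduce the cohort structure the analysis assumes:
    54.7% females; patient stratum weights 11.9/50.0/38.1%; per-stratum
    mean prescription counts 3.0/9.0/26.6 (so the strata carry roughly
    2/30/68% of prescriptions and the overall mean is ~15 per patient).
    """

    n_patients: int
    seed: int
    female_fraction: float = 0.547
    age_stratum_weights: tuple[float, float, float] = (0.119, 0.500, 0.381)
    prescriptions_per_patient: tuple[float, float, float] = (3.0, 9.0, 26.6)
    catalog_size: int = 800
    popularity_exponent: float = 1.4
    modules: tuple[ModuleSpec, ...] = field(default_factory=tuple)
    #: separate seed for the catalog, so cohorts can be re-drawn over a
    #: fixed catalog; defaults to ``seed``
    catalog_seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be a probability")
        w = self.age_stratum_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("age_stratum_weights must be 3 non-negative weights summing to 1")
        if sum(m.share for m in self.modules) > 1.0 + 1e-9:
            raise ValueError("module shares must sum to at most 1")


def generate_catalog(catalog_size: int, seed: int) -> list[ATCCode]:
    """Deterministically generate ``catalog_size`` distinct level-5 codes.

    Codes are spread over the 14 anatomical groups (round-robin over a
    seeded permutation, so any catalog of >= 14 codes covers all
    groups).  Catalog order encodes popularity rank: earlier codes are
    more popular under :func:`generate_records`.
    """
    if catalog_size < 1:
        raise ValueError("catalog_size must be >= 1")
    if catalog_size > _MAX_CATALOG:
        raise ValueError(f"catalog_size exceeds the level-5 code space ({_MAX_CATALOG})")
    rng = np.random.default_rng(seed)
    groups = rng.permutation(sorted(ANATOMICAL_GROUPS))
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    seen: set[str] = set()
    catalog: list[ATCCode] = []
    group_cycle = itertools.cycle(groups)
    while len(catalog) < catalog_size:
        g = next(group_cycle)
        text = (
            g
            + f"{rng.integers(100):02d}"
            + letters[rng.integers(26)]
            + letters[rng.integers(26)]
            + f"{rng.integers(100):02d}"
        )
        if text not in seen:
            seen.add(text)
            catalog.append(parse_atc(text))
    return catalog


def generate_records(cfg: SimConfig) -> list[PrescriptionRecord]:
    """Simulate one observation window of dispensation records.

    Every patient receives at least one prescription (so the cohort
    size equals ``cfg.n_patients``).  Drug choice follows a Zipf law
    over the catalog, ``weight ∝ rank^-popularity_exponent``; module
    patients mix in boosted within-module draws (see
    :class:`ModuleSpec`).
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = generate_catalog(
        cfg.catalog_size, cfg.seed if cfg.catalog_seed is None else cfg.catalog_seed
    )
    if not catalog:
        raise ValueError("empty drug catalog")
    code_index = {c.text: i for i, c in enumerate(catalog)}
    for m in cfg.modules:
        unknown = [c for c in m.codes if c not in code_index]
        if unknown:
            raise ValueError(f"module codes not in catalog: {unknown}")

    weights = np.arange(1, len(catalog) + 1, dtype=float) ** -cfg.popularity_exponent
    weights /= weights.sum()
    module_idx = [np.array([code_index[c] for c in m.codes]) for m in cfg.modules]

    # per-patient demographics, vectorised
    n = cfg.n_patients
    is_female = rng.random(n) < cfg.female_fraction
    stratum = rng.choice(3, size=n, p=np.asarray(cfg.age_stratum_weights))
    ages = np.empty(n, dtype=int)
    for s, (lo, hi) in enumerate(AGE_RANGES):
        mask = stratum == s
        ages[mask] = rng.integers(lo, hi + 1, size=mask.sum())
    birth_years = INDEX_YEAR - ages

    means = np.asarray(cfg.prescriptions_per_patient)[stratum]
    n_rx = 1 + rng.poisson(np.maximum(means - 1.0, 0.0))

    shares = np.array([m.share for m in cfg.modules], dtype=float)
    probs = np.concatenate([shares, [1.0 - shares.sum()]])
    membership = rng.choice(len(cfg.modules) + 1, size=n, p=probs)  # last = none

    n_days = (WINDOW_END - WINDOW_START).days + 1
    records: list[PrescriptionRecord] = []
    for p in range(n):
        k = n_rx[p]
        m = membership[p]
        if m < len(cfg.modules) and cfg.modules[m].boost > 0:
            from_module = rng.random(k) < cfg.modules[m].boost
            draws = rng.choice(len(catalog), size=k, p=weights)
            draws[from_module] = rng.choice(module_idx[m], size=int(from_module.sum()))
        else:
            draws = rng.choice(len(catalog), size=k, p=weights)
        days = rng.integers(n_days, size=k)
        pid = f"P{p:06d}"
        sex = "F" if is_female[p] else "M"
        by = int(birth_years[p])
        for d, day in zip(draws, days):
            records.append(
                PrescriptionRecord(
                    patient_id=pid,
                    sex=sex,
                    birth_year=by,
                    date=WINDOW_START + _dt.timedelta(days=int(day)),
                    atc5=catalog[int(d)],
                )
            )
    return records


def records_to_csv(records: list[PrescriptionRecord], path) -> None:
    """Write records in the CSV dialect :func:`dpnkit.ingest.load_records` reads."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "sex", "birth_year", "date", "atc5"])
        for r in records:
            writer.writerow([r.patient_id, r.sex, r.birth_year, r.date.isoformat(), r.atc5.text])
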