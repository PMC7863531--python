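"""Synthetic shelter records and networks with realistic structure.

The generator emulates the statistical shape of multi-state U.S. shelter
intake/outcome data so every pipeline stage is testable without real
downloads:

* species mix ~55.8% dogs;
* outcome mixes per species — dogs: returned 43.3%, euthanized 20%,
  adopted the remainder; cats: adopted 46.1%, euthanized 20%, returned
  the remainder;
* stay-in-shelter days drawn per (species, gender, outcome) cell from a
  gamma distribution moment-matched to the cell's configured mean/SD
  (defaults below; the reported coefficients of variation exceed 1, i.e.
  right-skewed, which a gamma reproduces), truncated at 365 days;
* intake/outcome dates constructed to realize the drawn stay;
* dog ages negatively associated with stay length (older dogs tend to
  have shorter recorded stays in these data);
* an optional corrupted fraction (missing cells, negative stays) for
  exercising the cleaning strategies, about 4.5% by default.

Note the generator emits *true* stay days for returned animals; zeroing
them is the preprocessing step's business, matching the pipeline order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .allocator import ShelterNetwork
from .preprocessing import MAX_DAYS, classify_age, classify_size, load_breed_size_map
from .records import AnimalRecord

# Mean / SD of stay days per (species, gender, outcome).
DEFAULT_STAY_MOMENTS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("dog", "male", "adopted"): (21.87, 24.74),
    ("dog", "male", "returned"): (8.52, 15.74),
    ("dog", "male", "euthanized"): (10.69, 20.75),
    ("dog", "female", "adopted"): (21.17, 23.65),
    ("dog", "female", "returned"): (8.56, 15.31),
    ("dog", "female", "euthanized"): (9.64, 20.00),
    ("cat", "male", "adopted"): (37.75, 40.78),
    ("cat", "male", "returned"): (6.32, 13.69),
    ("cat", "male", "euthanized"): (6.59, 11.73),
    ("cat", "female", "adopted"): (29.68, 33.63),
    ("cat", "female", "returned"): (7.53, 16.83),
    ("cat", "female", "euthanized"): (7.15, 11.02),
}

DOG_SHARE = 63790 / 114256  # dog records / all records
DEFAULT_OUTCOME_MIX = {
    "dog": {"returned": 0.433, "euthanized": 0.20, "adopted": 1 - 0.433 - 0.20},
    "cat": {"adopted": 0.461, "euthanized": 0.20, "returned": 1 - 0.461 - 0.20},
}
DEFAULT_ERROR_RATE = 5436 / 119691  # corrupted fraction ~4.54%

DEFAULT_LOCATIONS = ("shelter_ca", "shelter_ky", "shelter_tx",
                     "shelter_co", "shelter_az")

DOG_BREEDS = (
    "chihuahua", "labrador retriever", "german shepherd", "pit bull terrier",
    "beagle", "dachshund", "boxer", "border collie", "shih tzu",
    "yorkshire terrier", "australian cattle dog", "siberian husky",
    "great dane", "poodle", "rottweiler", "jack russell terrier",
    "catahoula", "rat terrier",
)
CAT_BREEDS = (
    "domestic shorthair", "domestic mediumhair", "domestic longhair",
    "siamese", "maine coon", "russian blue", "manx", "snowshoe",
)
COLOR_POOL = (
    "black", "white", "brown", "blue", "tan", "chocolate", "gray", "cream",
    "orange", "black/white", "brown/white", "blue/white", "calico",
    "brown tabby",
)


@dataclass
class GeneratorConfig:
    n_records: int = 10000
    seed: int = 0
    dog_share: float = DOG_SHARE
    outcome_mix: dict = field(default_factory=lambda: {
        sp: dict(mix) for sp, mix in DEFAULT_OUTCOME_MIX.items()})
    stay_moments: dict = field(default_factory=lambda: dict(DEFAULT_STAY_MOMENTS))
    error_rate: float = 0.0
    locations: tuple = DEFAULT_LOCATIONS
    intake_start: date = date(2019, 1, 1)
    intake_span_days: int = 365

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not 0 <= self.dog_share <= 1:
            raise ValueError("dog_share outside [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate outside [0, 1)")
        for sp, mix in self.outcome_mix.items():
            tot = sum(mix.values())
            if any(p < 0 for p in mix.values()) or abs(tot - 1) > 1e-9:
                raise ValueError(f"outcome mix for {sp} does not sum to 1")
        for cell, (m, s) in self.stay_moments.items():
            if m <= 0 or s <= 0:
                raise ValueError(f"non-positive stay moments for {cell}")


def _draw_days(rng: np.random.Generator, mean: float, sd: float) -> int:
    # Gamma moment match: shape k = (mean/sd)^2, scale = sd^2/mean.
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return int(min(round(rng.gamma(shape, scale)), MAX_DAYS))


def _draw_age(rng: np.random.Generator, species: str, days: int) -> float:
    # Dogs: expected age falls as the drawn stay grows, producing the
    # qualitative "older dogs, shorter stays" association without touching
    # the per-cell stay moments.
    if species == "dog":
        mean_age = 0.5 + 4.5 * np.exp(-days / 150.0)
    else:
        mean_age = 3.0
    return float(min(round(rng.exponential(mean_age), 1), 20.0))


def generate_records(config: GeneratorConfig) -> list[AnimalRecord]:
    """Draw raw records from the configured mixtures. Deterministic under
    the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    records: list[AnimalRecord] = []
    for i in range(n):
        species = "dog" if rng.random() < config.dog_share else "cat"
        gender = "male" if rng.random() < 0.5 else "female"
        mix = config.outcome_mix[species]
        outcomes = sorted(mix)  # deterministic order
        outcome = str(rng.choice(outcomes, p=[mix[o] for o in outcomes]))
        mean, sd = config.stay_moments[(species, gender, outcome)]
        days = _draw_days(rng, mean, sd)
        age = _draw_age(rng, species, days)
        intake = config.intake_start + timedelta(
            days=int(rng.integers(0, config.intake_span_days)))
        breeds = DOG_BREEDS if species == "dog" else CAT_BREEDS
        breed = str(rng.choice(breeds))
        if rng.random() < 0.15:
            breed = breed + "/mix"
        records.append(AnimalRecord(
            animal_id=f"A{i:06d}",
            animal_type=species,
            breed_raw=breed,
            color_raw=str(rng.choice(COLOR_POOL)),
            gender=gender,
            age_years=age,
            intake_date=intake,
            outcome_date=intake + timedelta(days=days),
            outcome_type=outcome,
            location=str(rng.choice(list(config.locations))),
        ))

    # Deliberate corruption for cleaner testing: exactly round(n * rate)
    # rows get one defect each.
    n_bad = int(round(n * config.error_rate))
    if n_bad:
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        for j in bad_idx:
            r = records[j]
            defect = int(rng.integers(0, 4))
            if defect == 0:
                r.gender = None
            elif defect == 1:
                r.age_years = None
            elif defect == 2:
                r.color_raw = None
            else:  # negative stay
                r.outcome_date = r.intake_date - timedelta(
                    days=int(rng.integers(1, 30)))
                r.valid = False
    return records


def generate_network(
    n_shelters: int,
    seed: int = 0,
    cost_scale: float = 100.0,
    capacity_range: tuple[int, int] = (0, 5),
    animal_types: tuple = ("dog", "cat"),
    sizes: tuple = ("small", "medium", "large"),
) -> ShelterNetwork:
    """Random symmetric shelter network: non-negative costs with a zero
    diagonal, integer capacities uniform over ``capacity_range``."""
    if n_shelters < 1:
        raise ValueError("need at least one shelter")
    rng = np.random.default_rng(seed)
    shelters = [f"s{i}" for i in range(n_shelters)]
    upper = np.triu(rng.uniform(0.1, 1.0, size=(n_shelters, n_shelters)), k=1)
    costs = (upper + upper.T) * cost_scale
    lo, hi = capacity_range
    capacity = {
        (l, y, s): int(rng.integers(lo, hi + 1))
        for l in shelters for y in animal_types for s in sizes
    }
    return ShelterNetwork(shelters=shelters, relocation_cost=costs,
                          capacity=capacity)


# ---------------------------------------------------------------------------
# Planted signal
# ---------------------------------------------------------------------------

@dataclass
class PlantRule:
    """Rewrite rule: records whose binned ``feature`` equals ``value`` get
    the LOS class ``target`` with probability ``probability``."""

    feature: str  # animal_type | gender | size_category | age_category | location
    value: str
    target: str   # low | medium | high | very_high
    probability: float = 1.0


_CLASS_TO_OUTCOME_DAYS = {
    # target class -> (outcome_type, day range to draw from)
    "low": ("adopted", (0, 8)),
    "medium": ("adopted", (9, 42)),
    "high": ("adopted", (43, MAX_DAYS)),
    "very_high": ("euthanized", (1, 60)),
}


def _record_feature(record: AnimalRecord, feature: str,
                    breed_size_map: dict) -> str | None:
    if feature == "animal_type":
        return record.animal_type
    if feature == "gender":
        return record.gender
    if feature == "location":
        return record.location
    if feature == "age_category":
        return None if record.age_years is None else classify_age(record.age_years)
    if feature == "size_category":
        if record.breed_raw is None:
            return None
        from .preprocessing import normalize_breed
        return classify_size(normalize_breed(record.breed_raw, breed_size_map),
                             breed_size_map)
    raise ValueError(f"rule references unknown feature {feature!r}")


def plant_signal(records: list[AnimalRecord], rule: PlantRule,
                 seed: int = 0) -> list[AnimalRecord]:
    """Rewrite outcome/days so the rule holds at its stated probability.

    Returns new records (the input list is not mutated).  Used to plant a
    known generative dependence for classifier and feature-importance
    recovery tests.
    """
    if rule.target not in _CLASS_TO_OUTCOME_DAYS:
        raise ValueError(f"unknown target class {rule.target!r}")
    if not 0 <= rule.probability <= 1:
        raise ValueError("probability outside [0, 1]")
    if rule.feature not in ("animal_type", "gender", "location",
                            "age_category", "size_category"):
        raise ValueError(f"rule references unknown feature {rule.feature!r}")
    bsm = load_breed_size_map()
    rng = np.random.default_rng(seed)
    out = []
    outcome, (lo, hi) = _CLASS_TO_OUTCOME_DAYS[rule.target]
    for r in records:
        r2 = replace(r)
        feat = _record_feature(r2, rule.feature, bsm)
        if feat == rule.value and rng.random() < rule.probability:
            days = int(rng.integers(lo, hi + 1))
            r2.outcome_type = outcome
            if r2.intake_date is not None:
                r2.outcome_date = r2.intake_date + timedelta(days=days)
            r2.valid = True
        out.append(r2)
    return out
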