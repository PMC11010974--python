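"""Synthetic multicolor flow-cytometry cohorts.

Generates per-patient white-blood-cell event tables whose CD34+ compartment
is a mixture of HSPC subtypes (HSC/MPP, CLP, CMP, MEP, GMP, a leukemic-blast
population and an "other" progenitor pool) on top of CD34-negative
lymphocyte / monocyte / granulocyte background. Remission (CR) and
active-disease (AD) cohorts differ in their mixtures: AD marrow is enriched
for CD38-negative stem-like cells and for a CD45RA+/CD123+/PD-L1-high
blast population.

Fluorescence is drawn log-normally per marker (strictly positive, heavy
right tail — the standard shape of uncompensated cytometry intensities).
A configurable fraction of events are doublets (FSC-A inflated relative to
FSC-H) and a configurable fraction are dead (viability-dye bright), so the
pre-gating steps have realistic work to do.

Ground-truth population labels are returned in a side channel
(:attr:`Cohort.truth`) that the analysis pipeline never reads; it exists for
validation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .channels import CHANNELS, GROUP_AD, GROUP_CR, GROUP_COL, GROUPS, PATIENT_COL

__all__ = [
    "SubtypeProfile",
    "CohortSpec",
    "Cohort",
    "default_profiles",
    "default_mixture",
    "interpolate_mixtures",
    "sample_subtype_events",
    "generate_patient",
    "generate_cohort",
]

#: Raw-scale positivity cutoff the default profiles are calibrated against.
RAW_POSITIVITY_CUTOFF = 300.0
#: Upper bound of the CD123 "low" (weakly positive) band on the raw scale.
RAW_CD123_LOW_UPPER = 2000.0
#: Viability-dye intensity above which an event counts as dead.
RAW_VIABILITY_CUTOFF = 1000.0
#: Mean viability-dye intensity of the injected dead events.
DEAD_VIABILITY_MEAN = 5000.0
#: FSC-A inflation factor applied to injected doublets.
DOUBLET_FSC_FACTOR = 1.9

_FLUOR = ("CD34", "CD38", "CD45RA", "CD123", "PD-L1", "CD45")


@dataclass(frozen=True)
class SubtypeProfile:
    """Log-normal intensity model of one cell population.

    ``marker_means`` / ``marker_cvs`` cover the fluorescence channels plus
    the scatter base (keys ``FSC`` and ``SSC``) and ``VIABILITY``;
    ``positivity`` records the intended +/-/low call per analysis marker.
    """

    name: str
    marker_means: dict[str, float]
    marker_cvs: dict[str, float]
    positivity: dict[str, str]

    def __post_init__(self) -> None:
        required = set(_FLUOR) | {"VIABILITY", "FSC", "SSC"}
        missing = required - set(self.marker_means)
        if missing:
            raise ValueError(f"profile {self.name!r} missing channels: {sorted(missing)}")
        for ch, m in self.marker_means.items():
            if m <= 0:
                raise ValueError(f"profile {self.name!r}: nonpositive mean for {ch}")
        for marker, call in self.positivity.items():
            mean = self.marker_means[marker]
            if call == "+" and mean <= RAW_POSITIVITY_CUTOFF:
                raise ValueError(
                    f"profile {self.name!r}: {marker} declared '+' but mean "
                    f"{mean} is not above the positivity cutoff"
                )
            if call == "-" and mean >= RAW_POSITIVITY_CUTOFF:
                raise ValueError(
                    f"profile {self.name!r}: {marker} declared '-' but mean "
                    f"{mean} is not below the positivity cutoff"
                )


def _load_default_config() -> dict:
    text = resources.files("hspcmap.data").joinpath("default_profiles.yaml").read_text()
    return yaml.safe_load(text)


def default_profiles() -> dict[str, SubtypeProfile]:
    """Profiles shipped with the package (see ``data/default_profiles.yaml``)."""
    cfg = _load_default_config()
    out = {}
    for name, spec in cfg["profiles"].items():
        out[name] = SubtypeProfile(
            name=name,
            marker_means={k: float(v) for k, v in spec["means"].items()},
            marker_cvs={k: float(v) for k, v in spec["cvs"].items()},
            positivity=dict(spec["positivity"]),
        )
    return out


def default_mixture(group: str) -> dict[str, float]:
    """Default whole-sample population mixture for ``"CR"`` or ``"AD"``."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return {k: float(v) for k, v in _load_default_config()["mixtures"][group].items()}


def interpolate_mixtures(
    cr: dict[str, float], ad: dict[str, float], effect_size: float
) -> dict[str, float]:
    """Mixture at a given group-separation effect size.

    ``effect_size=0`` returns the CR mixture (no group difference, chance-level
    classification), ``effect_size=1`` the full AD mixture; intermediate values
    interpolate linearly, which preserves nonnegativity and the unit sum.
    """
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError("effect_size must lie in [0, 1]")
    keys = set(cr) | set(ad)
    return {
        k: (1.0 - effect_size) * cr.get(k, 0.0) + effect_size * ad.get(k, 0.0)
        for k in keys
    }


@dataclass
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    n_cr: int = 12
    n_ad: int = 9
    cells_per_patient: tuple[int, int] = (2000, 50000)
    cr_mixture: dict[str, float] = field(default_factory=lambda: default_mixture(GROUP_CR))
    ad_mixture: dict[str, float] = field(default_factory=lambda: default_mixture(GROUP_AD))
    seed: int = 0
    doublet_fraction: float = 0.05
    dead_fraction: float = 0.05
    profiles: dict[str, SubtypeProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if self.n_cr + self.n_ad < 2:
            raise ValueError("cohort needs at least two patients")
        lo, hi = self.cells_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_patient must be a nondecreasing range with min >= 1")
        for label, mix in (("cr_mixture", self.cr_mixture), ("ad_mixture", self.ad_mixture)):
            vals = np.asarray(list(mix.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{label}: proportions must be nonnegative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{label}: proportions must sum to 1 (got {vals.sum()!r})")
            unknown = set(mix) - set(self.profiles)
            if unknown:
                raise ValueError(f"{label}: unknown profiles {sorted(unknown)}")

    def mixture_for(self, group: str) -> dict[str, float]:
        if group == GROUP_CR:
            return self.cr_mixture
        if group == GROUP_AD:
            return self.ad_mixture
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")

    def to_dict(self) -> dict:
        """JSON/YAML-serializable form (profiles referenced by value)."""
        return {
            "n_cr": self.n_cr,
            "n_ad": self.n_ad,
            "cells_per_patient": list(self.cells_per_patient),
            "cr_mixture": self.cr_mixture,
            "ad_mixture": self.ad_mixture,
            "seed": self.seed,
            "doublet_fraction": self.doublet_fraction,
            "dead_fraction": self.dead_fraction,
        }


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draw parameterized by arithmetic mean and CV (CV=0 → constant)."""
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def sample_subtype_events(
    profile: SubtypeProfile,
    n: int,
    seed: int | np.random.Generator,
    doublet_fraction: float = 0.0,
    dead_fraction: float = 0.0,
    ratio_jitter: float = 0.03,
) -> pd.DataFrame:
    """Draw ``n`` raw events from one population profile.

    Markers are log-normal around the profile means. FSC-H follows the
    profile's FSC distribution; singlet FSC-A tracks FSC-H up to
    ``ratio_jitter`` relative noise while doublets get FSC-A inflated by
    :data:`DOUBLET_FSC_FACTOR`. Dead events redraw the viability channel
    from a bright distribution above :data:`RAW_VIABILITY_CUTOFF`.
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cols: dict[str, np.ndarray] = {}
    for ch in _FLUOR:
        cols[ch] = _lognormal(rng, profile.marker_means[ch], profile.marker_cvs[ch], n)
    cols["VIABILITY"] = _lognormal(
        rng, profile.marker_means["VIABILITY"], profile.marker_cvs["VIABILITY"], n
    )
    fsc = _lognormal(rng, profile.marker_means["FSC"], profile.marker_cvs["FSC"], n)
    ssc = _lognormal(rng, profile.marker_means["SSC"], profile.marker_cvs["SSC"], n)
    cols["FSC-H"] = fsc
    cols["FSC-A"] = fsc * (1.0 + ratio_jitter * rng.standard_normal(n))
    cols["SSC-A"] = ssc

    doublet = rng.random(n) < doublet_fraction
    cols["FSC-A"] = np.where(doublet, cols["FSC-A"] * DOUBLET_FSC_FACTOR, cols["FSC-A"])
    dead = rng.random(n) < dead_fraction
    if dead.any():
        bright = _lognormal(rng, DEAD_VIABILITY_MEAN, 0.5, int(dead.sum()))
        cols["VIABILITY"] = cols["VIABILITY"].copy()
        cols["VIABILITY"][dead] = bright

    df = pd.DataFrame({ch: cols[ch] for ch in CHANNELS})
    df["_doublet"] = doublet
    df["_dead"] = dead
    return df


def _patient_seed(spec_seed: int, index: int) -> int:
    """Deterministic per-patient child seed (kept below 2**31)."""
    ss = np.random.SeedSequence([spec_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_patient(
    spec: CohortSpec, group: str, patient_id: str, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One patient's event table plus the ground-truth side channel.

    The total event count is drawn log-uniformly from
    ``spec.cells_per_patient`` (patient cellularity in this setting spans
    orders of magnitude); each event's population is a categorical draw from
    the group mixture. The returned table carries ``patient_id`` and
    ``group`` on every row; the truth frame (population label, doublet and
    dead flags per event) is for validation only and is not part of the
    table the pipeline sees.
    """
    mixture = spec.mixture_for(group)
    rng = np.random.default_rng(seed)
    lo, hi = spec.cells_per_patient
    n = int(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    n = int(np.clip(n, lo, hi))

    names = sorted(mixture)
    probs = np.asarray([mixture[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    assignment = rng.choice(len(names), size=n, p=probs)

    parts = []
    labels = np.empty(n, dtype=object)
    for i, name in enumerate(names):
        idx = np.flatnonzero(assignment == i)
        if idx.size == 0:
            continue
        part = sample_subtype_events(
            spec.profiles[name],
            idx.size,
            rng,
            doublet_fraction=spec.doublet_fraction,
            dead_fraction=spec.dead_fraction,
        )
        part.index = idx
        parts.append(part)
        labels[idx] = name
    table = pd.concat(parts).sort_index() if parts else sample_subtype_events(
        spec.profiles[names[0]], 0, rng
    )
    table = table.reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "population": labels,
            "doublet": table.pop("_doublet").to_numpy(),
            "dead": table.pop("_dead").to_numpy(),
        }
    )
    table[PATIENT_COL] = patient_id
    table[GROUP_COL] = group
    return table, truth


@dataclass
class Cohort:
    """Generated cohort: event tables, per-patient metadata, truth labels."""

    tables: list[pd.DataFrame]
    metadata: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    def table_for(self, patient_id: str) -> pd.DataFrame:
        for t in self.tables:
            if t[PATIENT_COL].iat[0] == patient_id:
                return t
        raise KeyError(patient_id)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate all patients of a cohort, a pure function of the spec.

    Patient ids are ``CR01..`` / ``AD01..``; each patient's seed derives
    deterministically from ``spec.seed`` and the patient index.
    """
    tables, truth, meta = [], {}, []
    index = 0
    for group, count in ((GROUP_CR, spec.n_cr), (GROUP_AD, spec.n_ad)):
        for k in range(count):
            pid = f"{group}{k + 1:02d}"
            seed = _patient_seed(spec.seed, index)
            table, labels = generate_patient(spec, group, pid, seed)
            tables.append(table)
            truth[pid] = labels
            meta.append(
                {PATIENT_COL: pid, GROUP_COL: group, "n_events": len(table), "seed": seed}
            )
            index += 1
    return Cohort(tables=tables, metadata=pd.DataFrame(meta), truth=truth)
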