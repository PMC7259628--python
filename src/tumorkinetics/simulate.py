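"""Synthetic SLD-trajectory cohorts with an early-phase trial's scan structure.

Each simulated patient gets one pre-baseline scan, one baseline scan (both at
t <= 0, times drawn uniformly within configurable windows) and six-weekly
on-treatment scans.  Observed SLD follows the segmented exponential model

    y(t) = y0 * exp(r_g * t * I(t <= 0) + r_s * t * I(t > 0)) * exp(eps)

with lognormal multiplicative residual noise (``eps ~ N(0, sigma_res)`` on
the log scale).  True parameters are drawn per patient from phenotype-level
truncated-normal distributions and stored in separate :class:`TruthRecord`
objects so that ground truth never leaks into fitting code.

Scanning stops at the first visit meeting RECIST progression when the
dropout rule is active, which reproduces the empirical pattern that patients
with progressive disease contribute fewer on-treatment scans than responders.
New lesions are simulated as a per-visit Bernoulli event for progressor-type
phenotypes only; they trigger PD but do not alter the SLD itself.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import recist
from .errors import ScenarioError
from .io import DAYS_PER_MONTH, PatientSeries, ScanRecord

#: Six-weekly visit interval in months under the package's calendar convention.
SIX_WEEKS_MONTHS = 42.0 / DAYS_PER_MONTH

RESPONDER = "responder"
STABLE = "stable"
PROGRESSOR = "progressor"


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [lo, hi]; sd = 0 degenerates to mean."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class PhenotypeSpec:
    """Sampling rules for one latent patient phenotype."""

    name: str
    weight: float
    rg: TruncNormal
    #: On-treatment rate; ``None`` means r_s = r_g plus N(0, rs_jitter_sd)
    #: (the no-treatment-effect null).
    rs: TruncNormal | None = None
    rs_jitter_sd: float = 0.0
    new_lesion_hazard: float = 0.0  # per-visit Bernoulli probability
    visits: tuple[int, int] = (1, 12)  # scheduled on-treatment scans, inclusive

    def sample_rates(self, rng: np.random.Generator) -> tuple[float, float]:
        rg = float(self.rg.sample(rng, 1)[0])
        if self.rs is None:
            rs = rg + (rng.normal(0.0, self.rs_jitter_sd) if self.rs_jitter_sd else 0.0)
        else:
            rs = float(self.rs.sample(rng, 1)[0])
        return rg, rs


@dataclass
class CohortScenario:
    """Full description of one simulated study's conditions."""

    name: str
    n_patients: int
    phenotypes: list[PhenotypeSpec]
    #: Lognormal baseline-size parameters on the log-mm scale.
    y0_log_mean: float = math.log(60.0)
    y0_log_sd: float = 0.5
    sigma_res: float = 0.1  # residual SD of log-SLD
    prebaseline_window: tuple[float, float] = (-12.0, -0.86)
    baseline_window: tuple[float, float] = (-0.80, 0.0)
    visit_interval: float = SIX_WEEKS_MONTHS
    max_post_scans: int = 12
    stop_at_pd: bool = True  # dropout rule: no scans after first RECIST PD
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ScenarioError("n_patients", "must be positive")
        if not self.phenotypes:
            raise ScenarioError("phenotypes", "at least one phenotype is required")
        if any(p.weight < 0 for p in self.phenotypes) or not any(
            p.weight > 0 for p in self.phenotypes
        ):
            raise ScenarioError("phenotypes", "weights must be >= 0 with a positive sum")
        if self.sigma_res < 0:
            raise ScenarioError("sigma_res", "must be >= 0")
        if self.visit_interval <= 0:
            raise ScenarioError("visit_interval", "must be > 0")
        if self.max_post_scans < 1:
            raise ScenarioError("max_post_scans", "must be >= 1")
        lo, hi = self.prebaseline_window
        blo, bhi = self.baseline_window
        if lo > hi:
            raise ScenarioError("prebaseline_window", "min must be <= max")
        if blo > bhi:
            raise ScenarioError("baseline_window", "min must be <= max")
        if bhi > 0:
            raise ScenarioError("baseline_window", "baseline scans occur at t <= 0")
        if hi >= blo:
            raise ScenarioError(
                "prebaseline_window",
                "pre-baseline window must lie entirely before the baseline window",
            )
        for p in self.phenotypes:
            vlo, vhi = p.visits
            if not (1 <= vlo <= vhi <= self.max_post_scans):
                raise ScenarioError(
                    "phenotypes",
                    f"{p.name}: visits range {p.visits} must satisfy "
                    f"1 <= lo <= hi <= max_post_scans ({self.max_post_scans})",
                )


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth parameters for one simulated patient (kept apart from data)."""

    patient_id: str
    true_y0: float
    true_rg: float
    true_rs: float
    phenotype: str


def _true_log_sld(t: float, y0: float, rg: float, rs: float) -> float:
    rate = rg if t <= 0 else rs
    return math.log(y0) + rate * t


def generate_cohort(
    scenario: CohortScenario, seed: int | None = None
) -> tuple[list[PatientSeries], list[TruthRecord]]:
    """Draw one cohort; fully reproducible from ``seed`` (default scenario.seed).

    Every patient contributes exactly one pre-baseline scan, one baseline scan
    and between 1 and ``max_post_scans`` on-treatment scans at multiples of
    ``visit_interval``; the dropout rule truncates the schedule after the
    first RECIST PD visit.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    weights = np.array([p.weight for p in scenario.phenotypes], dtype=float)
    weights = weights / weights.sum()
    width = max(4, len(str(scenario.n_patients)))

    cohort: list[PatientSeries] = []
    truths: list[TruthRecord] = []
    for i in range(scenario.n_patients):
        pid = f"P{i + 1:0{width}d}"
        pheno = scenario.phenotypes[rng.choice(len(scenario.phenotypes), p=weights)]
        rg, rs = pheno.sample_rates(rng)
        y0 = float(rng.lognormal(scenario.y0_log_mean, scenario.y0_log_sd))

        t_pre = float(rng.uniform(*scenario.prebaseline_window))
        t_base = float(rng.uniform(*scenario.baseline_window))
        n_sched = int(rng.integers(pheno.visits[0], pheno.visits[1] + 1))
        t_post = [scenario.visit_interval * (k + 1) for k in range(n_sched)]

        def observe(t: float) -> float:
            noise = rng.normal(0.0, scenario.sigma_res) if scenario.sigma_res else 0.0
            return math.exp(_true_log_sld(t, y0, rg, rs) + noise)

        scans = [
            ScanRecord(pid, t_pre, observe(t_pre)),
            ScanRecord(pid, t_base, observe(t_base)),
        ]
        baseline_sld = scans[1].sld
        nadir = baseline_sld
        for t in t_post:
            new_lesion = (
                pheno.new_lesion_hazard > 0
                and bool(rng.random() < pheno.new_lesion_hazard)
            )
            sld = observe(t)
            scans.append(ScanRecord(pid, t, sld, new_lesion))
            if scenario.stop_at_pd:
                cat = recist.classify_visit(sld, baseline_sld, nadir, new_lesion)
                if cat == recist.PD:
                    break
            nadir = min(nadir, sld)

        cohort.append(PatientSeries(pid, scans))
        truths.append(TruthRecord(pid, y0, rg, rs, pheno.name))
    return cohort, truths


def truth_frame(truths: Iterable[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(t) for t in truths],
        columns=["patient_id", "true_y0", "true_rg", "true_rs", "phenotype"],
    )


def preset_scenarios(n_patients: int = 68, seed: int = 0) -> dict[str, CohortScenario]:
    """Named study conditions.

    ``trial_like``
        A mixed cohort patterned on an early-phase monotherapy expansion:
        ~24% responders (shrinking on treatment, 1-3 scheduled post-baseline
        scans), ~24% on-treatment-stable patients and ~52% progressors (new
        lesions possible, scans stop at first PD).  Rate distributions are
        truncated normals centred on the responder / non-responder summary
        rates observed in such trials.
    ``tisd``
        Therapeutically induced stable disease: every tumor grows briskly
        pre-treatment (r_g > 0.05 month^-1) and is arrested on treatment
        (r_s ~ 0), with no new lesions.
    ``null``
        No treatment effect: r_s = r_g patient-by-patient, pure noise in d.
    """
    trial_like = CohortScenario(
        name="trial_like",
        n_patients=n_patients,
        seed=seed,
        phenotypes=[
            PhenotypeSpec(
                name=RESPONDER,
                weight=0.24,
                rg=TruncNormal(-0.040, 0.13, -0.427, 0.133),
                rs=TruncNormal(-0.454, 0.21, -0.911, -0.143),
                visits=(1, 3),
            ),
            PhenotypeSpec(
                name=STABLE,
                weight=0.24,
                rg=TruncNormal(0.040, 0.08, -0.20, 0.30),
                rs=None,
                rs_jitter_sd=0.02,
                visits=(1, 12),
            ),
            PhenotypeSpec(
                name=PROGRESSOR,
                weight=0.52,
                rg=TruncNormal(0.057, 0.15, -0.468, 0.517),
                rs=TruncNormal(0.12, 0.20, -0.20, 1.05),
                new_lesion_hazard=0.15,
                visits=(1, 12),
            ),
        ],
    )
    tisd = CohortScenario(
        name="tisd",
        n_patients=n_patients,
        seed=seed,
        sigma_res=0.05,
        stop_at_pd=False,
        phenotypes=[
            PhenotypeSpec(
                name=STABLE,
                weight=1.0,
                rg=TruncNormal(0.20, 0.05, 0.08, 0.40),
                rs=TruncNormal(0.0, 0.01, -0.03, 0.03),
                visits=(4, 8),
            )
        ],
    )
    null = CohortScenario(
        name="null",
        n_patients=n_patients,
        seed=seed,
        stop_at_pd=False,
        phenotypes=[
            PhenotypeSpec(
                name=STABLE,
                weight=1.0,
                rg=TruncNormal(0.034, 0.15, -0.468, 0.517),
                rs=None,
                visits=(4, 8),
            )
        ],
    )
    return {"trial_like": trial_like, "tisd": tisd, "null": null}


# ---------------------------------------------------------------------------
# Scenario files (plain-text key-value, YAML syntax)

def scenario_to_file(scenario: CohortScenario, path: str | Path) -> None:
    payload = dataclasses.asdict(scenario)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _trunc_from(d) -> TruncNormal:
    return TruncNormal(**d) if isinstance(d, dict) else d


def scenario_from_file(path: str | Path) -> CohortScenario:
    payload = yaml.safe_load(Path(path).read_text())
    phenos = []
    for p in payload.pop("phenotypes", []):
        p = dict(p)
        p["rg"] = _trunc_from(p["rg"])
        if p.get("rs") is not None:
            p["rs"] = _trunc_from(p["rs"])
        if "visits" in p:
            p["visits"] = tuple(p["visits"])
        phenos.append(PhenotypeSpec(**p))
    for key in ("prebaseline_window", "baseline_window"):
        if key in payload:
            payload[key] = tuple(payload[key])
    scenario = CohortScenario(phenotypes=phenos, **payload)
    scenario.validate()
    return scenario
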