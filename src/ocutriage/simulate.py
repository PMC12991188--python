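"""Synthetic vignette-cohort simulator.

No record-level data from the implementation study were ever deposited, so
the evaluation pipeline is exercised on synthetic cohorts instead.  A
cohort is built from a pool of clinically coherent vignette archetypes —
each a complaint category, a noiseless answer script for the default
questionnaire and a ground-truth acuity level — sampled to match the
analyzed population's structure: complaint-category weights 95:82:22:12,
a ~25% urgent (within-24-hours) prevalence, ages truncated-normal
(mean 53.5, SD 17.5, bounds 13-90), a telephone completion fraction of
19/136, voluntary 5-point Likert feedback from ~70% of patients with 82%
of respondents in the top two points, and completion times lognormal
around 4 min 57 s.

Observation noise enters through three channels, each independently
seeded from one root seed: answer noise (a patient's scripted choice is
resampled among the question's other options), an optometry-triager
sensitivity/specificity error model, and per-reviewer error models whose
defaults were chosen, via the closed-form two-rater kappa, to give
between-reviewer agreement near kappa = 0.40 at 25% prevalence.

Ground-truth columns in the output table carry a ``truth_`` prefix and are
never consumed by the evaluation module; they exist only for
parameter-recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .acuity import (
    AcuityLevel,
    AcuityTable,
    Service,
    load_default_table,
    triage,
)
from .errors import DefinitionError, TriageError
from .questionnaire import (
    QuestionGraph,
    load_default_graph,
    run_script,
    session_to_dict,
)

Script = tuple[tuple[str, tuple[str, ...]], ...]


@dataclass(frozen=True)
class VignetteArchetype:
    archetype_id: str
    category: str
    script: Script
    level: AcuityLevel
    emergency_class: bool

    @property
    def urgent(self) -> bool:
        return self.level.is_urgent_24h


def load_archetypes(
    graph: QuestionGraph,
    table: AcuityTable,
    source: Optional[str | Path] = None,
) -> tuple[VignetteArchetype, ...]:
    """Load the vignette pool and verify each against the engine.

    Every archetype's noiseless script must be a valid traversal whose
    engine disposition urgency equals the declared ground-truth level —
    the pool is rejected otherwise.
    """
    path = Path(source) if source else Path(__file__).parent / "data" / "archetypes.yaml"
    doc = yaml.safe_load(path.read_text())
    pool: list[VignetteArchetype] = []
    for adoc in doc["archetypes"]:
        script: Script = tuple(
            (step["question"], tuple(step["options"]))
            for step in adoc["script"]
        )
        arch = VignetteArchetype(
            archetype_id=str(adoc["id"]),
            category=str(adoc["category"]),
            script=script,
            level=AcuityLevel[str(adoc["level"])],
            emergency_class=bool(adoc.get("emergency_class", False)),
        )
        session = run_script(graph, arch.script, order_reference=f"check-{arch.archetype_id}")
        dispo = triage(session, graph, table)
        if dispo.urgency is not arch.level:
            raise DefinitionError(
                f"archetype {arch.archetype_id!r}: declared level "
                f"{arch.level.name} but engine assigns {dispo.urgency.name}"
            )
        pool.append(arch)
    return tuple(pool)


@dataclass
class CohortParams:
    """Generator settings; defaults emulate the analyzed study population."""

    n: int = 209
    category_weights: dict = field(default_factory=lambda: {
        "red_painful": 95, "visual_disturbance": 82,
        "eyelid": 22, "injury": 12,
    })
    urgent_prevalence: float = 0.25
    age_mean: float = 53.5
    age_sd: float = 17.5
    age_min: int = 13
    age_max: int = 90
    telephone_fraction: float = 19 / 136
    mode_missing_p: float = 0.0
    feedback_response_p: float = 147 / 209
    top2_p: float = 0.82
    duration_mean_s: float = 297.0
    duration_sd_s: float = 122.0
    duration_min_s: float = 90.0
    duration_max_s: float = 975.0
    answer_noise_rate: float = 0.05
    opt_sens: float = 0.77
    opt_spec: float = 0.80
    reviewer_sens: float = 0.83
    reviewer_spec: float = 0.85
    start_date: date = date(2025, 1, 6)
    study_days: int = 150
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "urgent_prevalence": self.urgent_prevalence,
            "telephone_fraction": self.telephone_fraction,
            "mode_missing_p": self.mode_missing_p,
            "feedback_response_p": self.feedback_response_p,
            "top2_p": self.top2_p,
            "answer_noise_rate": self.answer_noise_rate,
            "opt_sens": self.opt_sens, "opt_spec": self.opt_spec,
            "reviewer_sens": self.reviewer_sens,
            "reviewer_spec": self.reviewer_spec,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise TriageError(f"{name} must be in [0, 1], got {value}")
        if self.n < 1:
            raise TriageError("n must be >= 1")
        if any(w <= 0 for w in self.category_weights.values()):
            raise TriageError("category weights must be positive")


def perturb_answers(
    script: Sequence[tuple[str, Sequence[str]]],
    graph: QuestionGraph,
    noise_rate: float,
    rng: np.random.Generator,
) -> Script:
    """Resample scripted choices with probability ``noise_rate`` each.

    A perturbed single-select choice is drawn uniformly among the
    question's *other* options; a multi-select choice becomes a different
    non-empty option subset.  The perturbed script is re-walked through
    the graph, so questions newly reached by rerouting receive uniform
    random answers and the result is always a valid traversal.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise TriageError(f"noise_rate must be in [0, 1], got {noise_rate}")
    scripted = {qid: tuple(opts) for qid, opts in script}
    answers: dict[str, tuple[str, ...]] = {}
    out: list[tuple[str, tuple[str, ...]]] = []
    position = graph.entry
    from .questionnaire import TERMINAL
    while position != TERMINAL:
        question = graph.question(position)
        option_ids = [o.option_id for o in question.options]
        if position in scripted:
            chosen = scripted[position]
            if noise_rate > 0 and rng.random() < noise_rate:
                chosen = _resample_choice(question, chosen, rng)
        else:
            # question reached only because rerouting changed the path
            if question.select_mode == "single":
                chosen = (option_ids[int(rng.integers(len(option_ids)))],)
            else:
                chosen = _random_subset(option_ids, rng)
        answers[position] = chosen
        out.append((position, chosen))
        position = graph.successor(position, answers)
    return tuple(out)


def _random_subset(option_ids: Sequence[str], rng: np.random.Generator) -> tuple[str, ...]:
    while True:
        mask = rng.random(len(option_ids)) < 0.5
        if mask.any():
            return tuple(o for o, m in zip(option_ids, mask) if m)


def _resample_choice(
    question, current: tuple[str, ...], rng: np.random.Generator
) -> tuple[str, ...]:
    option_ids = [o.option_id for o in question.options]
    if question.select_mode == "single":
        others = [o for o in option_ids if o not in current]
        return (others[int(rng.integers(len(others)))],)
    for _ in range(100):
        candidate = _random_subset(option_ids, rng)
        if set(candidate) != set(current):
            return candidate
    return current


def simulate_raters(
    truth: Sequence[bool],
    sens: float,
    spec: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary labels from a sensitivity/specificity error model.

    Each true-urgent case is labeled urgent with probability ``sens`` and
    each true-non-urgent case non-urgent with probability ``spec``,
    independently across cases.
    """
    truth_arr = np.asarray(truth, dtype=bool)
    u = rng.random(truth_arr.shape[0])
    return np.where(truth_arr, u < sens, u >= spec)


def expected_two_rater_kappa(sens: float, spec: float, prevalence: float) -> float:
    """Closed-form kappa between two independent raters sharing an error model."""
    p1 = prevalence * sens + (1 - prevalence) * (1 - spec)
    p11 = prevalence * sens ** 2 + (1 - prevalence) * (1 - spec) ** 2
    p00 = prevalence * (1 - sens) ** 2 + (1 - prevalence) * spec ** 2
    p_o = p11 + p00
    p_e = p1 ** 2 + (1 - p1) ** 2
    return (p_o - p_e) / (1 - p_e)


def _partition_pool(
    pool: Sequence[VignetteArchetype],
) -> dict[str, dict[bool, list[VignetteArchetype]]]:
    by_cat: dict[str, dict[bool, list[VignetteArchetype]]] = {}
    for arch in pool:
        by_cat.setdefault(arch.category, {True: [], False: []})[arch.urgent].append(arch)
    return by_cat


def sample_cohort(
    params: CohortParams,
    graph: Optional[QuestionGraph] = None,
    table: Optional[AcuityTable] = None,
    pool: Optional[Sequence[VignetteArchetype]] = None,
) -> pd.DataFrame:
    """Draw a fully reproducible record-level synthetic cohort.

    Category membership is multinomial at the given weights; within the
    categories that contain urgent archetypes, the urgent stratum is drawn
    with the common probability that makes the overall urgent prevalence
    hit the target (a parameter error if the pool cannot reach it).  Each
    patient's session is produced by executing the questionnaire on the
    (possibly noise-perturbed) archetype script; optometry and reviewer
    labels come from their error models, with a third independent casting
    draw adjudicating reviewer disagreements.
    """
    params.validate()
    graph = graph or load_default_graph()
    table = table or load_default_table()
    pool = tuple(pool) if pool is not None else load_archetypes(graph, table)
    by_cat = _partition_pool(pool)

    categories = list(params.category_weights)
    missing_cats = set(categories) - set(by_cat)
    if missing_cats:
        raise TriageError(
            f"archetype pool has no vignette for category {sorted(missing_cats)}"
        )
    weights = np.array([params.category_weights[c] for c in categories], float)
    weights = weights / weights.sum()

    # common within-category urgent draw probability solving
    # sum_{c with urgent archetypes} w_c * u = target prevalence
    urgent_mass = sum(
        w for c, w in zip(categories, weights) if by_cat[c][True]
    )
    if params.urgent_prevalence > 0 and urgent_mass == 0:
        raise TriageError(
            "archetype pool contains no urgent vignette; cannot meet the "
            f"urgent-prevalence target {params.urgent_prevalence}"
        )
    u_prob = params.urgent_prevalence / urgent_mass if urgent_mass else 0.0
    if u_prob > 1.0 + 1e-12:
        raise TriageError(
            f"urgent-prevalence target {params.urgent_prevalence} is "
            f"unreachable: categories with urgent vignettes carry only "
            f"{urgent_mass:.3f} of the category mass"
        )
    u_prob = min(u_prob, 1.0)

    rng = np.random.default_rng(params.seed)
    age_dist = sps.truncnorm(
        (params.age_min - params.age_mean) / params.age_sd,
        (params.age_max - params.age_mean) / params.age_sd,
        loc=params.age_mean, scale=params.age_sd,
    )
    # lognormal matched to the target completion-time mean and SD
    cv2 = (params.duration_sd_s / params.duration_mean_s) ** 2
    sigma = float(np.sqrt(np.log1p(cv2)))
    mu = float(np.log(params.duration_mean_s) - sigma ** 2 / 2)

    rows = []
    sessions = []
    for i in range(params.n):
        cat = categories[int(rng.choice(len(categories), p=weights))]
        stratum_urgent = bool(by_cat[cat][True]) and (rng.random() < u_prob)
        options = by_cat[cat][stratum_urgent]
        if not options:  # category without the drawn stratum
            options = by_cat[cat][not stratum_urgent]
        arch = options[int(rng.integers(len(options)))]

        age = int(np.clip(round(age_dist.rvs(random_state=rng)),
                          params.age_min, params.age_max))
        known_mode = rng.random() >= params.mode_missing_p
        mode = ("telephone"
                if rng.random() < params.telephone_fraction else "online")
        script = perturb_answers(arch.script, graph,
                                 params.answer_noise_rate, rng)
        start_day = params.start_date + timedelta(
            days=int(rng.integers(params.study_days)))
        started = datetime(start_day.year, start_day.month, start_day.day,
                           int(rng.integers(8, 18)), int(rng.integers(60)),
                           tzinfo=timezone.utc)
        duration = float(np.clip(rng.lognormal(mu, sigma),
                                 params.duration_min_s, params.duration_max_s))
        session = run_script(
            graph, script, age=age, mode=mode,
            order_reference=f"SIM-{i + 1:05d}",
            started_at=started,
            finished_at=started + timedelta(seconds=duration),
        )
        dispo = triage(session, graph, table)

        truth_urgent = arch.urgent
        opt_urgent = bool(simulate_raters([truth_urgent], params.opt_sens,
                                          params.opt_spec, rng)[0])
        r1 = bool(simulate_raters([truth_urgent], params.reviewer_sens,
                                  params.reviewer_spec, rng)[0])
        r2 = bool(simulate_raters([truth_urgent], params.reviewer_sens,
                                  params.reviewer_spec, rng)[0])
        tiebreak = None
        if r1 != r2:
            tiebreak = bool(simulate_raters([truth_urgent],
                                            params.reviewer_sens,
                                            params.reviewer_spec, rng)[0])
        adjudicated = r1 if r1 == r2 else tiebreak

        if opt_urgent:
            opt_service, opt_urgency = (
                (Service.ED_EEC, AcuityLevel.EMERGENCY_SAME_DAY)
                if arch.emergency_class
                else (Service.MECS_CUES, AcuityLevel.URGENT_24H)
            )
        else:
            opt_service, opt_urgency = (
                Service.COMMUNITY_OPTOMETRY, AcuityLevel.ROUTINE_WEEK
            )

        likert = np.nan
        if rng.random() < params.feedback_response_p:
            if rng.random() < params.top2_p:
                likert = 5 if rng.random() < 0.61 else 4
            else:
                r = rng.random()
                likert = 3 if r < 0.78 else (2 if r < 0.94 else 1)

        rows.append({
            "order_reference": session.order_reference,
            "date": start_day.isoformat(),
            "age": age,
            "mode": mode if known_mode else "",
            "category": cat,
            "duration_s": duration,
            "likert": likert,
            "tool_service": dispo.service.value,
            "tool_urgency": dispo.urgency.name,
            "tool_urgent": dispo.urgency.is_urgent_24h,
            "opt_service": opt_service.value,
            "opt_urgency": opt_urgency.name,
            "opt_urgent": opt_urgent,
            "reviewer1_urgent": r1,
            "reviewer2_urgent": r2,
            "tiebreak_urgent": tiebreak if tiebreak is not None else np.nan,
            "adjudicated_urgent": adjudicated,
            "truth_archetype": arch.archetype_id,
            "truth_level": arch.level.name,
            "truth_urgent": truth_urgent,
        })
        sessions.append(session)

    frame = pd.DataFrame(rows)
    frame.attrs["sessions"] = sessions
    frame.attrs["params"] = asdict(params)
    return frame


def observed_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """The cohort table with every ground-truth column stripped."""
    return cohort[[c for c in cohort.columns if not c.startswith("truth_")]]


def write_cohort(cohort: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write the record-level CSV, per-patient session JSONs and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "records.csv"
    cohort.to_csv(csv_path, index=False)
    params = cohort.attrs.get("params", {})
    manifest = {k: (v.isoformat() if isinstance(v, date) else v)
                for k, v in params.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    sessions = cohort.attrs.get("sessions", [])
    if sessions:
        sess_dir = out / "sessions"
        sess_dir.mkdir(exist_ok=True)
        for session in sessions:
            (sess_dir / f"{session.order_reference}.json").write_text(
                json.dumps(session_to_dict(session), indent=2)
            )
    return csv_path
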