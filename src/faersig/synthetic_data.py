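"""Synthetic FAERS-format data with known ground truth.

The generator emulates the features of spontaneous reporting that the
pipeline must cope with: multi-drug multi-reaction reports, demographic
marginals, cross-quarter duplicate reports sharing a CASEID, and planted
drug-event associations of configurable strength.

Generative model, per report:

1. demographics drawn independently from the configured facet margins
   (defaults: the case-set distribution of the worked example, rescaled);
2. a drug set: each catalog drug independently with its background
   exposure probability (one weighted fallback drug if the set came up
   empty); one drug is primary suspect, the rest secondary suspects;
3. the target event with probability ``min(1, q0 * prod(lambda_d))`` over
   the planted drugs present, where ``q0`` is the baseline target-event
   probability implied by the PT catalog — a multiplicative effect on the
   conditional event probability, which is exactly the quantity the
   reporting-ratio statistics estimate.  A report with the event carries
   exactly one target PT (weighted); non-target PTs are independent
   background draws, with a weighted fallback so every report has at
   least one reaction;
4. with probability ``duplicate_rate`` the case is re-reported later:
   same CASEID and content, later FDA_DT, higher PRIMARYID — exactly the
   key the deduplication rule operates on.

Ground truth records the planted multipliers, the analytic report-level
odds ratio each planted drug should show, the realized report-level 2x2
table, and the exact duplicate pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .contingency import ContingencyTable
from .faers_io import write_quarter
from .records import UNKNOWN, AEReport
from .reference import DEMOGRAPHIC_COUNTS

DEFAULT_DRUG_CATALOG: dict[str, float] = {
    "acetaminophen": 0.60,
    "aspirin": 0.45,
    "metformin": 0.35,
    "atorvastatin": 0.30,
    "lisinopril": 0.25,
    "omeprazole": 0.20,
    "levothyroxine": 0.15,
    "amlodipine": 0.12,
    "ibuprofen": 0.10,
    "sertraline": 0.08,
    "prednisone": 0.07,
    "gabapentin": 0.06,
}

#: background reaction PTs; the three nerve-palsy terms are the target event
DEFAULT_PT_CATALOG: dict[str, float] = {
    "peroneal nerve palsy": 0.004,
    "radial nerve palsy": 0.003,
    "ulnar nerve palsy": 0.003,
    "nausea": 0.30,
    "headache": 0.25,
    "fatigue": 0.20,
    "dizziness": 0.18,
    "rash": 0.15,
    "vomiting": 0.12,
    "diarrhoea": 0.12,
    "pruritus": 0.08,
    "insomnia": 0.07,
    "arthralgia": 0.07,
    "dyspnoea": 0.06,
    "pyrexia": 0.06,
    "anxiety": 0.05,
    "myalgia": 0.05,
    "cough": 0.04,
}

DEFAULT_TARGET_TERMS = ("peroneal nerve palsy", "radial nerve palsy", "ulnar nerve palsy")

DEFAULT_QUARTERS = tuple(f"{yy:02d}Q{q}" for yy in (21, 22, 23, 24) for q in (1, 2, 3, 4))

_OTHER_COUNTRIES = ("France", "Italy", "Spain", "Brazil", "Australia",
                    "Netherlands", "Sweden", "China", "India", "Mexico")

# numeric value drawn uniformly within the band when a banded margin is sampled
_AGE_RANGES = {
    "0-20": (0.0, 20.0), "21-30": (20.0, 30.0), "31-40": (30.0, 40.0),
    "41-50": (40.0, 50.0), "51-60": (50.0, 60.0), "61-70": (60.0, 70.0),
    "71-80": (70.0, 80.0), ">80": (80.0, 95.0),
}
_WEIGHT_RANGES = {"<50": (30.0, 50.0), "50-100": (50.0, 100.0), ">100": (100.0, 140.0)}


def default_margins() -> dict[str, dict[str, float]]:
    """Facet margins of the worked example's case set, rescaled to probabilities."""
    margins = {}
    for facet, counts in DEMOGRAPHIC_COUNTS.items():
        total = sum(counts.values())
        margins[facet] = {level: n / total for level, n in counts.items()}
    return margins


@dataclass(frozen=True)
class PlantedSignal:
    """A drug whose presence multiplies the target-event probability by lam."""

    drug: str
    lam: float  # relative reporting ratio, >= 1
    target_event: bool = True


@dataclass
class SyntheticConfig:
    n_reports: int = 10_000
    quarters: tuple[str, ...] = DEFAULT_QUARTERS
    drug_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_CATALOG))
    pt_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PT_CATALOG))
    target_terms: tuple[str, ...] = DEFAULT_TARGET_TERMS
    planted_signals: tuple[PlantedSignal, ...] = ()
    demographic_margins: dict[str, dict[str, float]] = field(default_factory=default_margins)
    duplicate_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        for name, p in {**self.drug_catalog, **self.pt_catalog}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range for {name!r}: {p}")
        for sig in self.planted_signals:
            if sig.lam < 1.0:
                raise ValueError(f"planted lambda must be >= 1, got {sig.lam} for {sig.drug}")
        for facet, dist in self.demographic_margins.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"margins for facet {facet!r} sum to {total}, expected 1")

    def base_event_prob(self) -> float:
        """Baseline probability that an unexposed report carries the target event."""
        q0 = 1.0
        for term in self.target_terms:
            q0 *= 1.0 - self.pt_catalog[term]
        return 1.0 - q0


@dataclass
class GroundTruth:
    planted: dict[str, float]  # drug -> nominal lambda
    realized_multiplier: dict[str, float]  # after the min(1, q0*lam) cap
    true_odds_ratio: dict[str, float]  # analytic report-level OR per planted drug
    duplicate_pairs: list[tuple[str, str]]  # (original primaryid, duplicate primaryid)
    realized_tables: dict[str, ContingencyTable]  # report-level, unique cases
    base_event_prob: float
    n_unique: int


def calibration_config(seed: int, n_reports: int = 50_000) -> SyntheticConfig:
    """The standard parameter-recovery scenario: twelve null background drugs
    plus two planted drugs at 2% exposure with relative reporting ratios 2
    and 10 against a ~1% baseline target-event probability."""
    catalog = dict(DEFAULT_DRUG_CATALOG)
    catalog["siponimod"] = 0.02
    catalog["dalfampridine"] = 0.02
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=catalog,
        planted_signals=(
            PlantedSignal("siponimod", 2.0),
            PlantedSignal("dalfampridine", 10.0),
        ),
    )


def _quarter_range(tag: str) -> tuple[date, date]:
    yy, q = int(tag[:2]), int(tag[3])
    year = 2000 + yy if yy < 70 else 1900 + yy
    start = date(year, 3 * (q - 1) + 1, 1)
    end = date(year + (q == 4), 1 if q == 4 else 3 * q + 1, 1) - timedelta(days=1)
    return start, end


def quarter_of(fda_dt: int) -> str:
    """Quarter tag (YYQq) of a YYYYMMDD date integer."""
    year, month = fda_dt // 10000, (fda_dt // 100) % 100
    return f"{year % 100:02d}Q{(month - 1) // 3 + 1}"


def _true_odds_ratio(config: SyntheticConfig, drug: str) -> float:
    """Analytic report-level odds ratio for one planted drug.

    Exposure probabilities follow the independent-Bernoulli catalog draw
    (including the empty-set fallback for the drug itself); co-exposure to
    the other planted drugs is treated as independent, which is exact up
    to the fallback's O(P_empty * p_drug) perturbation.
    """
    q0 = config.base_event_prob()
    lam = {s.drug: s.lam for s in config.planted_signals}
    others = [d for d in lam if d != drug]

    def event_prob(exposed: bool) -> float:
        prob = 0.0
        for combo in itertools.product([0, 1], repeat=len(others)):
            w = 1.0
            mult = lam[drug] if exposed else 1.0
            for o, on in zip(others, combo):
                p_o = config.drug_catalog[o]
                w *= p_o if on else (1.0 - p_o)
                if on:
                    mult *= lam[o]
            prob += w * min(1.0, q0 * mult)
        return prob

    q1, q_not = event_prob(True), event_prob(False)
    if q1 >= 1.0:  # saturated (capped) event probability: odds are infinite
        return math.inf
    return (q1 / (1.0 - q1)) / (q_not / (1.0 - q_not))


def generate(config: SyntheticConfig) -> tuple[list[AEReport], GroundTruth]:
    """Draw a pre-dedup report list and its ground truth; reproducible from seed.

    Stage-keyed random substreams (demographics, drugs, reactions, dates,
    duplicates) are spawned from the config seed, so each stage's draws do
    not depend on how many values another stage consumed.
    """
    config.validate()
    n = config.n_reports
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_demo, rng_drug, rng_reac, rng_date, rng_dup = (np.random.default_rng(s) for s in streams)

    # --- demographics -----------------------------------------------------
    def draw(facet: str) -> np.ndarray:
        dist = config.demographic_margins[facet]
        levels = list(dist)
        return rng_demo.choice(len(levels), size=n, p=[dist[k] for k in levels]), levels

    sex_idx, sex_levels = draw("gender")
    age_idx, age_levels = draw("age")
    wt_idx, wt_levels = draw("weight")
    rep_idx, rep_levels = draw("reporter")
    cty_idx, cty_levels = draw("country")
    out_idx, out_levels = draw("outcome")
    age_u = rng_demo.random(n)
    wt_u = rng_demo.random(n)
    other_cty = rng_demo.choice(len(_OTHER_COUNTRIES), size=n)

    # --- drug sets --------------------------------------------------------
    drug_names = list(config.drug_catalog)
    drug_probs = np.array([config.drug_catalog[d] for d in drug_names])
    exposure = rng_drug.random((n, len(drug_names))) < drug_probs
    empty = ~exposure.any(axis=1)
    if empty.any():
        fallback = rng_drug.choice(
            len(drug_names), size=int(empty.sum()), p=drug_probs / drug_probs.sum()
        )
        exposure[np.flatnonzero(empty), fallback] = True

    # --- reactions --------------------------------------------------------
    lam = {s.drug: s.lam for s in config.planted_signals}
    q0 = config.base_event_prob()
    for d, lm in lam.items():
        if q0 * lm > 1.0:
            warnings.warn(
                f"planted multiplier for {d!r} saturates the event probability "
                f"(q0*lambda = {q0 * lm:.2f} > 1); capped at 1", stacklevel=2
            )
    mult = np.ones(n)
    for d, lm in lam.items():
        mult[exposure[:, drug_names.index(d)]] *= lm
    p_event = np.minimum(1.0, q0 * mult)
    event = rng_reac.random(n) < p_event

    target_terms = list(config.target_terms)
    target_w = np.array([config.pt_catalog[t] for t in target_terms])
    target_pick = rng_reac.choice(len(target_terms), size=n, p=target_w / target_w.sum())

    bg_terms = [t for t in config.pt_catalog if t not in config.target_terms]
    bg_probs = np.array([config.pt_catalog[t] for t in bg_terms])
    bg_draw = rng_reac.random((n, len(bg_terms))) < bg_probs
    no_bg = ~bg_draw.any(axis=1)
    bg_fallback = rng_reac.choice(
        len(bg_terms), size=n, p=bg_probs / bg_probs.sum()
    )

    # --- dates ------------------------------------------------------------
    q_idx = rng_date.choice(len(config.quarters), size=n)
    day_u = rng_date.random(n)
    dup_mask = rng_dup.random(n) < config.duplicate_rate
    dup_delay = rng_dup.integers(10, 200, size=n)

    ranges = [_quarter_range(tag) for tag in config.quarters]

    reports: list[AEReport] = []
    duplicates: list[AEReport] = []
    dup_pairs: list[tuple[str, str]] = []
    for i in range(n):
        caseid = str(1_000_001 + i)
        primaryid = caseid + "1"
        start, end = ranges[q_idx[i]]
        fda = start + timedelta(days=int(day_u[i] * ((end - start).days + 1)))

        age_lab = age_levels[age_idx[i]]
        if age_lab == UNKNOWN:
            age = None
        else:
            lo, hi = _AGE_RANGES[age_lab]
            age = lo + age_u[i] * (hi - lo)
        wt_lab = wt_levels[wt_idx[i]]
        if wt_lab == UNKNOWN:
            wt = None
        else:
            lo, hi = _WEIGHT_RANGES[wt_lab]
            wt = lo + wt_u[i] * (hi - lo)
        country = cty_levels[cty_idx[i]]
        if country == "Other-Country":
            country = _OTHER_COUNTRIES[other_cty[i]]

        names = [drug_names[j] for j in np.flatnonzero(exposure[i])]
        drugs = [(nm, "PS" if k == 0 else "SS") for k, nm in enumerate(names)]

        reactions = {bg_terms[j] for j in np.flatnonzero(bg_draw[i])}
        if event[i]:
            reactions.add(target_terms[target_pick[i]])
        elif no_bg[i]:
            reactions.add(bg_terms[bg_fallback[i]])

        rep = AEReport(
            primaryid=primaryid,
            caseid=caseid,
            fda_dt=int(fda.strftime("%Y%m%d")),
            sex=sex_levels[sex_idx[i]],
            age_years=age,
            weight_kg=wt,
            reporter=rep_levels[rep_idx[i]],
            country=country,
            outcome=out_levels[out_idx[i]],
            drugs=drugs,
            reactions=reactions,
        )
        reports.append(rep)
        if dup_mask[i]:
            later = fda + timedelta(days=int(dup_delay[i]))
            dup = AEReport(
                primaryid=caseid + "2",
                caseid=caseid,
                fda_dt=int(later.strftime("%Y%m%d")),
                sex=rep.sex,
                age_years=rep.age_years,
                weight_kg=rep.weight_kg,
                reporter=rep.reporter,
                country=rep.country,
                outcome=rep.outcome,
                drugs=list(rep.drugs),
                reactions=set(rep.reactions),
            )
            duplicates.append(dup)
            dup_pairs.append((primaryid, dup.primaryid))

    # --- ground truth -----------------------------------------------------
    realized_tables = {}
    for d in lam:
        col = drug_names.index(d)
        a = int((exposure[:, col] & event).sum())
        b = int((exposure[:, col] & ~event).sum())
        c = int((~exposure[:, col] & event).sum())
        realized_tables[d] = ContingencyTable(a, b, c, n - a - b - c)

    truth = GroundTruth(
        planted={d: lm for d, lm in lam.items()},
        realized_multiplier={d: min(1.0, q0 * lm) / q0 for d, lm in lam.items()},
        true_odds_ratio={d: _true_odds_ratio(config, d) for d in lam},
        duplicate_pairs=dup_pairs,
        realized_tables=realized_tables,
        base_event_prob=q0,
        n_unique=n,
    )
    return reports + duplicates, truth


def split_by_quarter(reports: list[AEReport]) -> dict[str, list[AEReport]]:
    """Group reports into quarterly file sets by FDA receipt date."""
    out: dict[str, list[AEReport]] = {}
    for rep in reports:
        out.setdefault(quarter_of(rep.fda_dt), []).append(rep)
    return out


def exact_margin_reports(counts: dict[str, dict[str, int]] | None = None) -> list[AEReport]:
    """A deterministic case set whose facet counts equal the given tallies exactly.

    Defaults to the worked example's published demographic table; every
    facet must sum to the same case total.  Attributes are assigned
    independently per facet (the joint distribution is arbitrary; only the
    margins are meaningful).  The ``Other-Country`` tally is spread over a
    pool of countries kept rarer than the named top five.
    """
    counts = counts or DEMOGRAPHIC_COUNTS
    totals = {facet: sum(d.values()) for facet, d in counts.items()}
    if len(set(totals.values())) != 1:
        raise ValueError(f"facet totals differ: {totals}")
    n = next(iter(totals.values()))

    def expand(facet: str) -> list[str]:
        out: list[str] = []
        for level, cnt in counts[facet].items():
            if facet == "country" and level == "Other-Country":
                share, rem = divmod(cnt, len(_OTHER_COUNTRIES))
                for j, name in enumerate(_OTHER_COUNTRIES):
                    out.extend([name] * (share + (1 if j < rem else 0)))
            else:
                out.extend([level] * cnt)
        return out

    age_rep = {lab: (lo + hi) / 2 for lab, (lo, hi) in _AGE_RANGES.items()}
    wt_rep = {"<50": 45.0, "50-100": 75.0, ">100": 110.0}
    cols = {facet: expand(facet) for facet in counts}
    reports = []
    for i in range(n):
        reports.append(
            AEReport(
                primaryid=f"{9_000_001 + i}1",
                caseid=str(9_000_001 + i),
                fda_dt=20240101,
                sex=cols["gender"][i],
                age_years=None if cols["age"][i] == UNKNOWN else age_rep[cols["age"][i]],
                weight_kg=None if cols["weight"][i] == UNKNOWN else wt_rep[cols["weight"][i]],
                reporter=cols["reporter"][i],
                country=cols["country"][i],
                outcome=cols["outcome"][i],
                drugs=[("drug x", "PS")],
                reactions={"peroneal nerve palsy"},
            )
        )
    return reports


def _micro4() -> list[AEReport]:
    """Four hand-enumerated reports covering multi-drug, multi-PT and a case."""
    return [
        AEReport("101", "1", 20240115, sex="F", age_years=55.0, weight_kg=70.0,
                 reporter="consumer", country="United States", outcome="HO",
                 drugs=[("drug a", "PS"), ("drug b", "SS")],
                 reactions={"peroneal nerve palsy", "nausea", "headache"}),
        AEReport("201", "2", 20240120, sex="M", age_years=60.0,
                 reporter="health-professional", country="Canada", outcome="OT",
                 drugs=[("drug a", "PS")], reactions={"nausea"}),
        AEReport("301", "3", 20240201, sex="F",
                 drugs=[("drug c", "PS"), ("drug b", "C")],
                 reactions={"radial nerve palsy"}),
        AEReport("401", "4", 20240210, sex="M", age_years=20.0,
                 drugs=[("drug b", "PS")], reactions={"rash", "fatigue"}),
    ]


def _dup_pair_set() -> list[AEReport]:
    base = _micro4()[:2]
    dup = AEReport("102", "1", 20240301, sex="F", age_years=55.0, weight_kg=70.0,
                   reporter="consumer", country="United States", outcome="HO",
                   drugs=[("drug a", "PS"), ("drug b", "SS")],
                   reactions={"peroneal nerve palsy", "nausea", "headache"})
    return base + [dup]


def write_fixture_suite(dir_path: str | Path) -> dict[str, Path]:
    """Emit the small canned scenarios used across module tests.

    ``micro4``: four hand-enumerated reports; ``dups``: a cross-quarter
    duplicate pair; ``orphans``: a quarter whose DRUG file carries one row
    with a report id absent from DEMO.  Re-running produces identical
    bytes.
    """
    dir_path = Path(dir_path)
    scenarios: dict[str, Path] = {}

    for name, reports in (("micro4", _micro4()), ("dups", _dup_pair_set())):
        sub = dir_path / name
        write_quarter(reports, sub, "24Q1")
        scenarios[name] = sub

    sub = dir_path / "orphans"
    write_quarter(_micro4(), sub, "24Q1")
    with (sub / "DRUG24Q1.txt").open("a", encoding="utf-8") as fh:
        fh.write("999$99$1$PS$drug z\n")
    scenarios["orphans"] = sub
    return scenarios
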