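"""Synthetic FAERS-style databases with planted ground truth.

The generator emulates the structure the pipeline consumes — ``$``-delimited
DEMO/DRUG/REAC/INDI quarterly files with duplicate case versions, suspect and
concomitant role codes, and salt/hydrate drug-name variants — while keeping
the joint law of (drugs, events) simple enough to admit a closed-form oracle:

* each drug enters a report independently with its marginal probability, so
  drugs-per-report follows the induced Poisson-binomial law;
* each event enters with probability ``min(1, baseline * theta_eff)`` where
  ``theta_eff`` aggregates the reporting-rate multipliers theta(drug, event)
  of the report's drugs (maximum by default, product optionally);
  ``theta == 1`` everywhere means no planted association.

``expected_lnror`` evaluates the asymptotic lnROR of a pair exactly by
enumerating the inclusion patterns of the drugs relevant to the event, which
is what parameter-recovery tests compare estimates against.  Probability
capping (baseline * theta > 1) is counted during generation and rejected by
the oracle, since a capped pair has no closed form of this shape.

Everything is reproducible: a config with the same seed yields byte-identical
files.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = ["DrugSpec", "EventSpec", "SyntheticConfig", "GroundTruth",
           "CappedPairError", "simulate", "write_faers_files", "generate",
           "expected_cell_probs", "expected_lnror", "DEFAULT_NAME_TEMPLATES"]

#: Name-variant templates applied to a drug label when rendering DRUG rows.
DEFAULT_NAME_TEMPLATES = (
    "{}",
    "{} HYDROCHLORIDE",
    "{} SULFATE",
    "{} HCL",
    "{} TARTRATE",
    "{} hydrochloride",
)


class CappedPairError(ValueError):
    """The pair's inclusion probability saturates at 1; no closed-form lnROR."""


@dataclass(frozen=True)
class DrugSpec:
    """One generator drug: canonical label, marginal report probability, and
    the verbatim name variants it may be rendered as."""

    label: str
    prob: float
    variants: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"drug {self.label!r}: prob must be in [0, 1]")

    def render_pool(self) -> tuple[str, ...]:
        if self.variants is not None:
            return self.variants
        return tuple(t.format(self.label.upper()) for t in DEFAULT_NAME_TEMPLATES)


@dataclass(frozen=True)
class EventSpec:
    """One adverse-event preferred term with its baseline report probability."""

    term: str
    prob: float

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"event {self.term!r}: prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    n_reports: int
    drugs: tuple[DrugSpec, ...]
    events: tuple[EventSpec, ...]
    #: (drug label, event term) -> reporting-rate multiplier theta >= 0.
    #: Unlisted pairs default to 1 (no association).
    multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    aggregation: str = "max"            # multi-drug aggregation: "max" or "product"
    duplicate_rate: float = 0.05        # fraction of cases with a superseded version
    concomitant_prob: float = 0.2       # chance of one extra concomitant-role DRUG row
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.aggregation not in ("max", "product"):
            raise ValueError("aggregation must be 'max' or 'product'")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        for (d, e), th in self.multipliers.items():
            if th < 0:
                raise ValueError(f"multiplier for ({d!r}, {e!r}) must be >= 0")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "multipliers", dict(self.multipliers))

    def theta(self, drug: str, event: str) -> float:
        return self.multipliers.get((drug, event), 1.0)


@dataclass
class GroundTruth:
    """Per-report truth: which drugs and events each report carries."""

    config: SyntheticConfig
    drug_labels: tuple[str, ...]
    event_terms: tuple[str, ...]
    drug_matrix: np.ndarray     # (n_reports, n_drugs) bool
    event_matrix: np.ndarray    # (n_reports, n_events) bool
    n_capped: int = 0           # report-event cells whose probability hit the cap

    def pair_counts(self, drug: str, event: str) -> tuple[int, int, int, int]:
        """Raw partition cells (a, b, c, d) under the other-reports comparator."""
        i = self.drug_labels.index(drug)
        j = self.event_terms.index(event)
        dcol = self.drug_matrix[:, i]
        ecol = self.event_matrix[:, j]
        a = int(np.sum(dcol & ecol))
        b = int(np.sum(dcol)) - a
        c = int(np.sum(ecol)) - a
        d = int(self.drug_matrix.shape[0]) - a - b - c
        return a, b, c, d


def simulate(config: SyntheticConfig) -> GroundTruth:
    """Draw the report x drug and report x event membership matrices."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    labels = tuple(d.label for d in config.drugs)
    terms = tuple(e.term for e in config.events)
    probs = np.array([d.prob for d in config.drugs])
    X = rng.random((n, len(labels))) < probs[None, :]

    Y = np.zeros((n, len(terms)), dtype=bool)
    n_capped = 0
    for j, ev in enumerate(config.events):
        # theta_eff aggregates the multipliers of the report's drugs (absent
        # entries count as 1); a report with no drugs keeps theta_eff = 1.
        th = np.array([config.theta(d.label, ev.term) for d in config.drugs])
        if len(th) == 0 or np.all(th == 1.0):
            theta_eff = np.ones(n)
        elif config.aggregation == "max":
            masked = np.where(X, th[None, :], -np.inf)
            m = masked.max(axis=1)
            theta_eff = np.where(np.isneginf(m), 1.0, m)
        else:
            theta_eff = np.prod(np.where(X, th[None, :], 1.0), axis=1)
        p = ev.prob * theta_eff
        n_capped += int(np.sum(p > 1.0))
        Y[:, j] = rng.random(n) < np.minimum(p, 1.0)

    return GroundTruth(config=config, drug_labels=labels, event_terms=terms,
                       drug_matrix=X, event_matrix=Y, n_capped=n_capped)


DEMO_HEADER = "primaryid$caseid$age$sex$reporter_country"
DRUG_HEADER = "primaryid$caseid$drug_seq$role_cod$drugname"
REAC_HEADER = "primaryid$caseid$pt"
INDI_HEADER = "primaryid$caseid$indi_drug_seq$indi_pt"

_INDICATIONS = ("PAIN MANAGEMENT", "ANAESTHESIA", "DIARRHOEA", "COUGH",
                "PRODUCT USED FOR UNKNOWN INDICATION")


def write_faers_files(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Render the ground truth as the four ``$``-delimited quarterly files.

    Case ``i`` (1-based) gets primaryid ``i*100 + version``; a fraction
    ``duplicate_rate`` of cases also emit a superseded version 1 whose DEMO row
    differs only in demographics (drug and reaction content is identical, so a
    dedup bug shows up purely as an inflated report count).  Suspect rows get
    role PS or SS at random; with probability ``concomitant_prob`` a report
    carries one extra concomitant (role C) drug row that ingestion must drop.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA]))
    n = config.n_reports
    pools = [d.render_pool() for d in config.drugs]
    all_names = [name for pool in pools for name in pool]
    sexes = ("F", "M", "UNK")
    countries = ("US", "JP", "GB", "DE", "FR")

    dup = rng.random(n) < config.duplicate_rate
    ages = rng.integers(18, 95, size=n)
    sex_idx = rng.integers(0, len(sexes), size=n)
    ctry_idx = rng.integers(0, len(countries), size=n)

    paths = {kind: outdir / f"{kind}.txt" for kind in ("DEMO", "DRUG", "REAC", "INDI")}
    with open(paths["DEMO"], "w", encoding="latin-1", newline="\n") as demo, \
         open(paths["DRUG"], "w", encoding="latin-1", newline="\n") as drug, \
         open(paths["REAC"], "w", encoding="latin-1", newline="\n") as reac, \
         open(paths["INDI"], "w", encoding="latin-1", newline="\n") as indi:
        demo.write(DEMO_HEADER + "\n")
        drug.write(DRUG_HEADER + "\n")
        reac.write(REAC_HEADER + "\n")
        indi.write(INDI_HEADER + "\n")
        for r in range(n):
            caseid = str(r + 1)
            version = 2 if dup[r] else 1
            pid = str((r + 1) * 100 + version)
            if dup[r]:
                old_pid = str((r + 1) * 100 + 1)
                old_age = int(ages[r]) - 1 if ages[r] > 18 else int(ages[r]) + 1
                demo.write(f"{old_pid}${caseid}${old_age}${sexes[sex_idx[r]]}$"
                           f"{countries[ctry_idx[r]]}\n")
            demo.write(f"{pid}${caseid}${int(ages[r])}${sexes[sex_idx[r]]}$"
                       f"{countries[ctry_idx[r]]}\n")

            versions = ((old_pid, pid) if dup[r] else (pid,))
            drug_idx = np.flatnonzero(truth.drug_matrix[r])
            lines = []
            seq = 0
            for i in drug_idx:
                seq += 1
                name = pools[i][rng.integers(0, len(pools[i]))]
                role = "PS" if rng.random() < 0.7 else "SS"
                lines.append((seq, role, name))
            if rng.random() < config.concomitant_prob and all_names:
                seq += 1
                name = all_names[rng.integers(0, len(all_names))]
                lines.append((seq, "C", name))
            for v in versions:
                for seq_, role, name in lines:
                    drug.write(f"{v}${caseid}${seq_}${role}${name}\n")

            terms = [truth.event_terms[j] for j in np.flatnonzero(truth.event_matrix[r])]
            for v in versions:
                for pt in terms:
                    reac.write(f"{v}${caseid}${pt}\n")

            if drug_idx.size:
                ind = _INDICATIONS[rng.integers(0, len(_INDICATIONS))]
                indi.write(f"{pid}${caseid}$1${ind}\n")
    return paths


def generate(config: SyntheticConfig, outdir: str | Path
             ) -> tuple[dict[str, Path], GroundTruth]:
    """Simulate and write the file set plus a ground-truth sidecar (JSON)."""
    truth = simulate(config)
    paths = write_faers_files(truth, outdir)
    sidecar = Path(outdir) / "ground_truth.json"
    with open(sidecar, "w", encoding="utf-8", newline="\n") as fh:
        json.dump({
            "seed": config.seed,
            "n_reports": config.n_reports,
            "drugs": [{"label": d.label, "prob": d.prob} for d in config.drugs],
            "events": [{"term": e.term, "prob": e.prob} for e in config.events],
            "multipliers": [
                {"drug": d, "event": e, "theta": th}
                for (d, e), th in sorted(config.multipliers.items())
            ],
            "aggregation": config.aggregation,
            "duplicate_rate": config.duplicate_rate,
            "n_capped": truth.n_capped,
            "drug_report_counts": {
                lab: int(truth.drug_matrix[:, i].sum())
                for i, lab in enumerate(truth.drug_labels)
            },
            "event_report_counts": {
                term: int(truth.event_matrix[:, j].sum())
                for j, term in enumerate(truth.event_terms)
            },
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["ground_truth"] = sidecar
    return paths, truth


# -- closed-form oracle -----------------------------------------------------

def expected_cell_probs(config: SyntheticConfig, drug: str, event: str
                        ) -> tuple[float, float, float, float]:
    """Asymptotic partition-cell probabilities (p_a, p_b, p_c, p_d) for a pair.

    Enumerates inclusion patterns of the drugs relevant to the event (the
    target plus every drug with theta != 1 for it); all other drugs cannot
    change the event probability and integrate out.  Raises
    :class:`CappedPairError` if any reachable pattern saturates the
    probability.
    """
    ev = next((e for e in config.events if e.term == event), None)
    if ev is None:
        raise KeyError(f"event {event!r} not in the generator's event vocabulary")
    drugs_by_label = {d.label: d for d in config.drugs}
    if drug not in drugs_by_label:
        raise KeyError(f"drug {drug!r} not in the generator's drug vocabulary")

    relevant = {drug} | {d for (d, e) in config.multipliers if e == event
                         and config.multipliers[(d, e)] != 1.0
                         and d in drugs_by_label}
    relevant = sorted(relevant)
    if len(relevant) > 20:
        raise ValueError("too many drugs with non-unit multipliers for "
                         "closed-form enumeration")
    # Under "max" aggregation a present non-relevant drug (theta = 1) lifts
    # the maximum to >= 1, so its presence matters whenever every present
    # relevant drug has theta < 1.
    p_other_any = 1.0 - math.prod(
        1.0 - d.prob for d in config.drugs if d.label not in relevant)

    p_a = p_e = 0.0
    target_pos = relevant.index(drug)
    for pattern in itertools.product((False, True), repeat=len(relevant)):
        prob = 1.0
        thetas = []
        for lab, present in zip(relevant, pattern):
            p = drugs_by_label[lab].prob
            prob *= p if present else (1.0 - p)
            if present:
                thetas.append(config.theta(lab, event))
        if prob == 0.0:
            continue
        if config.aggregation == "product":
            cases = [(1.0, math.prod(thetas) if thetas else 1.0)]
        elif not thetas:
            cases = [(1.0, 1.0)]    # no drugs, or only theta-1 drugs
        else:
            t_rel = max(thetas)
            if t_rel >= 1.0:
                cases = [(1.0, t_rel)]
            else:
                cases = [(p_other_any, 1.0), (1.0 - p_other_any, t_rel)]
        for case_prob, theta_eff in cases:
            if case_prob == 0.0:
                continue
            pe_pattern = ev.prob * theta_eff
            if pe_pattern > 1.0:
                raise CappedPairError(
                    f"pair ({drug!r}, {event!r}): baseline {ev.prob} x theta_eff "
                    f"{theta_eff} exceeds 1; no closed-form expectation")
            p_e += prob * case_prob * pe_pattern
            if pattern[target_pos]:
                p_a += prob * case_prob * pe_pattern

    p_drug = drugs_by_label[drug].prob
    p_b = p_drug - p_a
    p_c = p_e - p_a
    p_d = 1.0 - p_a - p_b - p_c
    return p_a, p_b, p_c, p_d


def expected_lnror(config: SyntheticConfig, drug: str, event: str,
                   comparator: str = "all_reports") -> float:
    """Asymptotic lnROR implied by the generator under a comparator convention."""
    p_a, p_b, p_c, p_d = expected_cell_probs(config, drug, event)
    if comparator == "other_reports":
        num, den = p_a * p_d, p_b * p_c
    elif comparator == "all_reports":
        p_e = p_a + p_c
        num, den = p_a * (1.0 - p_e), p_b * p_e
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    if num == 0.0 or den == 0.0:
        raise ValueError(f"pair ({drug!r}, {event!r}) has a zero asymptotic cell; "
                         "lnROR undefined without correction")
    return math.log(num / den)
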