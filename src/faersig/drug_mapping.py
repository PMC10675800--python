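"""Normalizing verbatim FAERS drug-name strings to canonical drug labels.

FAERS drugnames are free text: the same substance appears as "MORPHINE",
"MORPHINE SULFATE", "morphine sulphate er", inside combination products, etc.
Mapping is by case-insensitive substring inclusion patterns with exclusion
vetoes, which resolves nested names (CODEINE inside DIHYDROCODEINE, MORPHINE
inside APOMORPHINE) without a dictionary.  The shipped default rules cover the
11 mu-opioid receptor agonists approved in Japan; a rules file with the same
structure extends the scheme to any drug list.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

__all__ = ["DrugRule", "load_rules", "default_rules", "map_drugname",
           "map_labels", "TARGET_OPIOIDS"]

#: Canonical labels of the 11 target mu-opioid agonists, in the shipped order.
TARGET_OPIOIDS = (
    "morphine", "fentanyl", "oxycodone", "codeine", "dihydrocodeine",
    "hydromorphone", "methadone", "tapentadol", "pethidine", "loperamide",
    "remifentanil",
)


@dataclass(frozen=True)
class DrugRule:
    """Substring inclusion/exclusion rule assigning one canonical label."""

    label: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.include:
            raise ValueError(f"rule {self.label!r} has no include patterns")
        object.__setattr__(self, "include", tuple(p.upper() for p in self.include))
        object.__setattr__(self, "exclude", tuple(p.upper() for p in self.exclude))

    def matches(self, verbatim_upper: str) -> bool:
        return (any(p in verbatim_upper for p in self.include)
                and not any(p in verbatim_upper for p in self.exclude))


def load_rules(path: str | Path) -> list[DrugRule]:
    """Load mapping rules from a YAML file (``rules: [{label, include, exclude}]``)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [DrugRule(label=r["label"],
                     include=tuple(r.get("include", ())),
                     exclude=tuple(r.get("exclude", ())))
            for r in doc["rules"]]


def default_rules() -> list[DrugRule]:
    """The in-package rules for the 11 target opioids."""
    ref = importlib.resources.files("faersig").joinpath("data/drug_rules.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_rules(path)


def map_drugname(verbatim: str, rules: Iterable[DrugRule]) -> set[str]:
    """Canonical labels matching one verbatim drug-name string.

    Empty set means a non-target drug; a combination-product string naming two
    targets yields both labels.
    """
    upper = verbatim.upper()
    return {rule.label for rule in rules if rule.matches(upper)}


def map_labels(drugnames: Iterable[str], rules: Iterable[DrugRule]) -> set[str]:
    """Union of labels over a report's verbatim suspect-drug names."""
    rules = list(rules)
    labels: set[str] = set()
    for name in drugnames:
        labels |= map_drugname(name, rules)
    return labels
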