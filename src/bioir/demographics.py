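"""Strict boolean demographic matching for clinical-trial retrieval.

A precision-medicine topic carries a demographic string such as
"38-year-old male"; each clinical-trial document carries structured
eligibility constraints (minimum/maximum age in years, accepted
gender).  The filter removes trials the patient cannot enrol in.

Missing information never excludes: absent trial age bounds are
unconstrained, a trial gender of "all" accepts everyone, and a profile
whose gender could not be parsed passes all gender checks.  Age bounds
are inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

from .corpus import InvertedIndex

__all__ = [
    "DemographicProfile",
    "TrialConstraints",
    "parse_demographic",
    "trial_matches",
    "apply_demographic_filter",
]

_AGE_RE = re.compile(r"(\d+)[\s-]*year[\s-]*old", re.IGNORECASE)
_GENDER_RE = re.compile(r"\b(male|female)\b", re.IGNORECASE)


@dataclass(frozen=True)
class DemographicProfile:
    """A patient's age in years and gender ("male"/"female"/"unknown")."""

    age: int | None = None
    gender: str = "unknown"

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError("age must be nonnegative")
        if self.gender not in ("male", "female", "unknown"):
            raise ValueError(f"invalid gender: {self.gender!r}")


@dataclass(frozen=True)
class TrialConstraints:
    """Eligibility constraints of a trial; None bounds are open."""

    min_age: int | None = None
    max_age: int | None = None
    gender: str = "all"

    def __post_init__(self) -> None:
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError("min_age exceeds max_age")
        if self.gender not in ("male", "female", "all"):
            raise ValueError(f"invalid trial gender: {self.gender!r}")


def parse_demographic(text: str) -> DemographicProfile:
    """Extract age and gender from a topic's demographic text.

    Age is the first integer preceding "-year-old" (or "year old");
    gender is the first whole-word occurrence of male/female, case
    insensitive.  If neither is found the filter cannot be applied and
    an error is raised.
    """
    age_match = _AGE_RE.search(text)
    gender_match = _GENDER_RE.search(text)
    if age_match is None and gender_match is None:
        raise ValueError(
            f"cannot parse age or gender from demographic text: {text!r}"
        )
    age = int(age_match.group(1)) if age_match else None
    gender = gender_match.group(1).lower() if gender_match else "unknown"
    return DemographicProfile(age=age, gender=gender)


def trial_matches(profile: DemographicProfile, constraints: TrialConstraints) -> bool:
    """True iff the patient satisfies the trial's age bounds
    (inclusive) and gender restriction; unknowns always pass."""
    if profile.age is not None:
        if constraints.min_age is not None and profile.age < constraints.min_age:
            return False
        if constraints.max_age is not None and profile.age > constraints.max_age:
            return False
    if (
        constraints.gender != "all"
        and profile.gender != "unknown"
        and profile.gender != constraints.gender
    ):
        return False
    return True


def apply_demographic_filter(
    profile: DemographicProfile, index: InvertedIndex
) -> Callable[[str], bool]:
    """Build the per-document predicate handed to search().

    Documents without eligibility fields are unconstrained and always
    pass; the filtered ranking is therefore a subset of the unfiltered
    one with relative order preserved.
    """

    def predicate(doc_id: str) -> bool:
        doc = index.documents.get(doc_id)
        if doc is None:
            return True
        constraints = TrialConstraints(
            min_age=doc.min_age,
            max_age=doc.max_age,
            gender=doc.gender if doc.gender is not None else "all",
        )
        return trial_matches(profile, constraints)

    return predicate
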