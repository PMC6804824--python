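"""Internal-standard quantification of GC-MS peak tables and aroma classification.

Contents are computed with the standard internal-standard formula

    content (ug/g) = (peak_area * is_amount / is_peak_area) / sample_weight

and relative percentages over the total emitted amount.  Compounds are
aggregated into five odor classes (herbal, fruity, cool, floral, spicy) and
cultivars assigned to one of six aroma groups (faint, cool, fruity, musky,
fruity-honey, lily) by a configurable ordered decision list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ODOR_CLASSES = ("herbal", "fruity", "cool", "floral", "spicy")
AROMA_GROUPS = ("faint", "cool", "fruity", "musky", "fruity-honey", "lily")

_RULE_FIELDS = frozenset(ODOR_CLASSES) | {"total"}
_RULE_OPS = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}

# Best-effort fit to the published six-group classification; thresholds are
# configuration, not a law (the published grouping also used sensory panels).
DEFAULT_RULES: list[dict] = [
    {"label": "faint", "all": [["total", "lt", 1.0]]},
    {"label": "cool", "all": [["cool", "ge", 40.0], ["fruity", "lt", 20.0]]},
    {"label": "musky", "all": [["cool", "ge", 20.0], ["cool+fruity", "ge", 55.0]]},
    {"label": "lily", "all": [["herbal", "ge", 20.0], ["fruity", "ge", 35.0]]},
    {"label": "fruity", "all": [["fruity", "ge", 55.0], ["cool", "lt", 5.0]]},
    {"label": "fruity-honey", "all": [["fruity", "ge", 40.0]]},
]


class InvalidPeakTable(ValueError):
    """Raised when a peak table violates its invariants."""


class RuleConfigError(ValueError):
    """Raised when a classification rule references an unknown field or operator."""


@dataclass
class PeakTable:
    """Raw GC-MS peak areas for one cultivar plus internal-standard bookkeeping.

    Parameters
    ----------
    cultivar_id : str
    entries : list of (compound_name, peak_area)
        Peak areas in arbitrary (but mutually consistent) area units.
    is_name : str
        Internal-standard compound (3-heptanone in the original protocol).
    is_amount : float
        Amount of internal standard added, ug.
    is_peak_area : float
        Internal-standard peak area, same units as ``entries``.
    sample_weight : float
        Fresh sample weight, g.
    """

    cultivar_id: str
    entries: list[tuple[str, float]]
    is_name: str
    is_amount: float
    is_peak_area: float
    sample_weight: float

    def __post_init__(self) -> None:
        if self.is_peak_area <= 0:
            raise InvalidPeakTable(
                f"{self.cultivar_id}: is_peak_area must be positive, got {self.is_peak_area}"
            )
        if self.sample_weight <= 0:
            raise InvalidPeakTable(
                f"{self.cultivar_id}: sample_weight must be positive, got {self.sample_weight}"
            )
        if self.is_amount <= 0:
            raise InvalidPeakTable(
                f"{self.cultivar_id}: is_amount must be positive, got {self.is_amount}"
            )
        names = [c for c, _ in self.entries]
        if len(names) != len(set(names)):
            raise InvalidPeakTable(f"{self.cultivar_id}: duplicate compound names in peak table")
        for name, area in self.entries:
            if area < 0:
                raise InvalidPeakTable(
                    f"{self.cultivar_id}: negative peak area for {name!r}: {area}"
                )


@dataclass
class VolatileProfile:
    """Per-cultivar absolute contents (ug/g) and relative percentages."""

    cultivar_id: str
    contents: dict[str, float]
    percents: dict[str, float]

    @property
    def total_content(self) -> float:
        return sum(self.contents.values())


@dataclass
class OdorMap:
    """Compound -> odor class lookup; unmapped compounds are an explicit miss."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c: k for c, k in self.entries.items() if k not in ODOR_CLASSES}
        if bad:
            raise ValueError(f"odor classes must be one of {ODOR_CLASSES}; offending: {bad}")

    def lookup(self, compound: str) -> str | None:
        return self.entries.get(compound)


@dataclass
class AromaProfile:
    """Five odor-class percentage sums and the assigned aroma group."""

    cultivar_id: str
    class_percents: tuple[float, float, float, float, float]
    total_content: float
    group: str = "unassigned"
    unmapped: list[str] = field(default_factory=list)
    unmapped_percent: float = 0.0


def quantify_content(table: PeakTable) -> VolatileProfile:
    """Convert peak areas to absolute contents (ug/g) and relative percents.

    An empty entry list yields an empty profile with total 0.
    """
    contents = {
        name: (area * table.is_amount / table.is_peak_area) / table.sample_weight
        for name, area in table.entries
    }
    total = sum(contents.values())
    if total > 0:
        percents = {name: 100.0 * c / total for name, c in contents.items()}
    else:
        percents = {name: 0.0 for name in contents}
    return VolatileProfile(table.cultivar_id, contents, percents)


def select_major_compounds(profiles: list[VolatileProfile], threshold: float = 10.0) -> set[str]:
    """Compounds whose relative percent strictly exceeds ``threshold`` in >=1 profile."""
    if not profiles:
        raise ValueError("select_major_compounds requires at least one profile")
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    major: set[str] = set()
    for p in profiles:
        major.update(name for name, pct in p.percents.items() if pct > threshold)
    return major


def aggregate_odor_classes(profile: VolatileProfile, odor_map: OdorMap) -> AromaProfile:
    """Sum compound percentages into the five odor classes.

    Compounds without an odor-class mapping contribute to no class; they are
    listed in ``unmapped`` with their total percentage so that
    class sums + unmapped percent == 100 whenever the profile total is > 0.
    """
    sums = dict.fromkeys(ODOR_CLASSES, 0.0)
    unmapped: list[str] = []
    unmapped_pct = 0.0
    for name, pct in profile.percents.items():
        cls = odor_map.lookup(name)
        if cls is None:
            unmapped.append(name)
            unmapped_pct += pct
        else:
            sums[cls] += pct
    return AromaProfile(
        cultivar_id=profile.cultivar_id,
        class_percents=tuple(sums[k] for k in ODOR_CLASSES),
        total_content=profile.total_content,
        unmapped=unmapped,
        unmapped_percent=unmapped_pct,
    )


def _eval_field(name: str, values: dict[str, float]) -> float:
    # "a+b" composite fields let a rule threshold a sum of classes
    parts = name.split("+")
    for p in parts:
        if p not in _RULE_FIELDS:
            raise RuleConfigError(f"unknown field {p!r} in rule field {name!r}")
    return sum(values[p] for p in parts)


def classify_aroma(aroma: AromaProfile, rules: list[dict] | None = None) -> str:
    """Return the label of the first matching rule, or ``"unassigned"``.

    ``rules`` is an ordered decision list; each rule is
    ``{"label": str, "all": [[field, op, value], ...]}`` with fields drawn from
    the five odor classes, ``total``, or ``+``-joined sums of classes, and ops
    in {lt, le, gt, ge}.  Classification is a pure function of
    (class_percents, total_content, rules).
    """
    if rules is None:
        rules = DEFAULT_RULES
    values = dict(zip(ODOR_CLASSES, aroma.class_percents))
    values["total"] = aroma.total_content
    for rule in rules:
        try:
            label = rule["label"]
            clauses = rule["all"]
        except (KeyError, TypeError) as exc:
            raise RuleConfigError(f"malformed rule {rule!r}") from exc
        ok = True
        for fieldname, op, threshold in clauses:
            if op not in _RULE_OPS:
                raise RuleConfigError(f"unknown operator {op!r} in rule {label!r}")
            if not _RULE_OPS[op](_eval_field(fieldname, values), float(threshold)):
                ok = False
                break
        if ok:
            return label
    return "unassigned"
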