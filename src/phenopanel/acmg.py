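"""ACMG/AMP evidence-criteria parsing and 5-tier combination.

Variants are classified on the 5-tier scale — benign (1), likely benign
(2), VUS (3), likely pathogenic (4), pathogenic (5) — by combining evidence
criteria.  Pathogenic-side codes: PVS1 (very strong), PS1-PS4 (strong),
PM1-PM6 (moderate), PP1-PP5 (supporting).  Benign-side codes: BA1
(stand-alone), BS1-BS4 (strong), BP1-BP7 (supporting).  A criterion may be
applied at a non-default strength via a suffix modifier, e.g. ``PVS1-m``
applies PVS1 at moderate strength.

Criteria *assignment* (deciding that PVS1 or PM1 applies to a variant) is
accepted as input — it needs transcript, hotspot and case-level evidence
outside this package's scope.  Only PM2 (absent/extremely rare in
population databases) has an advisory auto-assignment helper driven by the
gnomAD allele frequency.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .variant_filter import FilterConfig, VariantRecord

__all__ = [
    "CriteriaParseError",
    "Strength",
    "ACMGCriterion",
    "ACMGClassification",
    "parse_criteria",
    "combine_criteria",
    "auto_assign_pm2",
    "classify_table",
    "TIER_LABELS",
]

VERY_STRONG = "very_strong"
STRONG = "strong"
MODERATE = "moderate"
SUPPORTING = "supporting"
STAND_ALONE = "stand_alone_benign"

Strength = str

_DEFAULT_STRENGTH: dict[str, Strength] = {"PVS1": VERY_STRONG, "BA1": STAND_ALONE}
_DEFAULT_STRENGTH.update({f"PS{i}": STRONG for i in range(1, 5)})
_DEFAULT_STRENGTH.update({f"PM{i}": MODERATE for i in range(1, 7)})
_DEFAULT_STRENGTH.update({f"PP{i}": SUPPORTING for i in range(1, 6)})
_DEFAULT_STRENGTH.update({f"BS{i}": STRONG for i in range(1, 5)})
_DEFAULT_STRENGTH.update({f"BP{i}": SUPPORTING for i in range(1, 8)})

_MODIFIERS: dict[str, Strength] = {
    "vs": VERY_STRONG,
    "s": STRONG,
    "m": MODERATE,
    "p": SUPPORTING,
}

TIER_LABELS = {
    1: "benign",
    2: "likely_benign",
    3: "VUS",
    4: "likely_pathogenic",
    5: "pathogenic",
}

_TOKEN_RE = re.compile(r"^([A-Z]+\d+)(?:-([a-z]+))?$")


class CriteriaParseError(ValueError):
    """A criteria string contains an unknown or duplicate token."""


@dataclass(frozen=True)
class ACMGCriterion:
    """One evidence criterion with its default and applied strengths."""

    code: str
    default_strength: Strength
    applied_strength: Strength

    @property
    def benign_side(self) -> bool:
        return self.code.startswith("B")


@dataclass(frozen=True)
class ACMGClassification:
    """A 5-tier class with the combining rule (or conflict state) matched."""

    tier: int
    label: str
    rationale: str


def parse_criteria(text: str) -> list[ACMGCriterion]:
    """Parse a comma-separated criteria string like ``"PVS1-m, PM2"``.

    Each token is ``CODE`` or ``CODE-modifier`` with modifier in
    ``{vs, s, m, p}``.  Unknown codes/modifiers and duplicate codes raise
    :class:`CriteriaParseError`; token order is preserved.
    """
    criteria: list[ACMGCriterion] = []
    seen: set[str] = set()
    for raw in text.split(","):
        token = raw.strip()
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise CriteriaParseError(f"unparseable criteria token: {token!r}")
        code, modifier = m.group(1), m.group(2)
        if code not in _DEFAULT_STRENGTH:
            raise CriteriaParseError(f"unknown criterion code: {token!r}")
        if code in seen:
            raise CriteriaParseError(f"duplicate criterion code: {code}")
        seen.add(code)
        if modifier is None:
            applied = _DEFAULT_STRENGTH[code]
        elif modifier in _MODIFIERS:
            applied = _MODIFIERS[modifier]
        else:
            raise CriteriaParseError(f"unknown strength modifier: {token!r}")
        criteria.append(
            ACMGCriterion(
                code=code,
                default_strength=_DEFAULT_STRENGTH[code],
                applied_strength=applied,
            )
        )
    return criteria


def combine_criteria(criteria: Sequence[ACMGCriterion]) -> ACMGClassification:
    """Combine criteria (at their APPLIED strengths) into a 5-tier class.

    Implements the published combining rules.  Mixed pathogenic- and
    benign-side evidence without a stand-alone BA1 yields VUS with
    rationale ``conflicting_evidence``; no matching rule yields VUS
    ``insufficient_evidence``.  BA1 dominates any conflict.
    """
    path = Counter()
    benign = Counter()
    stand_alone = False
    for c in criteria:
        if c.code == "BA1" and c.applied_strength == STAND_ALONE:
            stand_alone = True
        elif c.benign_side:
            # benign combining rules use strong/supporting buckets only
            if c.applied_strength in (STRONG, VERY_STRONG):
                benign[STRONG] += 1
            else:
                benign[SUPPORTING] += 1
        else:
            path[c.applied_strength] += 1

    has_path = sum(path.values()) > 0
    has_benign = sum(benign.values()) > 0 or stand_alone

    if stand_alone:
        return ACMGClassification(1, TIER_LABELS[1], "BA1 stand-alone")
    if has_path and has_benign:
        return ACMGClassification(3, TIER_LABELS[3], "conflicting_evidence")

    vs, s = path[VERY_STRONG], path[STRONG]
    m, p = path[MODERATE], path[SUPPORTING]

    pathogenic_rules = [
        # the published table assumes a single very-strong criterion; two
        # (reachable via -vs upgrades) outweigh very_strong + strong
        (vs >= 2, ">=2 very_strong"),
        (vs >= 1 and s >= 1, "very_strong + >=1 strong"),
        (vs >= 1 and m >= 2, "very_strong + >=2 moderate"),
        (vs >= 1 and m == 1 and p == 1, "very_strong + 1 moderate + 1 supporting"),
        (vs >= 1 and p >= 2, "very_strong + >=2 supporting"),
        (s >= 2, ">=2 strong"),
        (s == 1 and m >= 3, "1 strong + >=3 moderate"),
        (s == 1 and m == 2 and p >= 2, "1 strong + 2 moderate + >=2 supporting"),
        (s == 1 and m == 1 and p >= 4, "1 strong + 1 moderate + >=4 supporting"),
    ]
    for hit, rationale in pathogenic_rules:
        if hit:
            return ACMGClassification(5, TIER_LABELS[5], rationale)

    likely_pathogenic_rules = [
        (vs >= 1 and m == 1, "very_strong + 1 moderate"),
        (s == 1 and 1 <= m <= 2, "1 strong + 1-2 moderate"),
        (s == 1 and p >= 2, "1 strong + >=2 supporting"),
        (m >= 3, ">=3 moderate"),
        (m == 2 and p >= 2, "2 moderate + >=2 supporting"),
        (m == 1 and p >= 4, "1 moderate + >=4 supporting"),
    ]
    for hit, rationale in likely_pathogenic_rules:
        if hit:
            return ACMGClassification(4, TIER_LABELS[4], rationale)

    bs, bp = benign[STRONG], benign[SUPPORTING]
    if bs >= 2:
        return ACMGClassification(1, TIER_LABELS[1], ">=2 benign strong")
    if (bs == 1 and bp >= 1) or bp >= 2:
        return ACMGClassification(
            2, TIER_LABELS[2], "benign strong + supporting" if bs else ">=2 benign supporting"
        )

    return ACMGClassification(3, TIER_LABELS[3], "insufficient_evidence")


def auto_assign_pm2(
    record: VariantRecord,
    config: FilterConfig | None = None,
    moi_context: str = "dominant",
) -> bool:
    """Advisory PM2 call: absent or extremely rare in population databases.

    True iff the gnomAD AF is absent or at/below the mode-of-inheritance
    context threshold (recessive context uses the laxer recessive cutoff).
    Advisory only — a provided criteria string is never overridden.
    """
    config = config or FilterConfig()
    if record.gnomad_af is None:
        return True
    threshold = (
        config.max_af_recessive
        if moi_context == "recessive"
        else config.max_af_dominant
    )
    return record.gnomad_af <= threshold


def classify_table(
    rows: Iterable,
) -> tuple[list[ACMGClassification], Counter]:
    """Classify a batch of rows carrying ``acmg_criteria`` strings.

    Returns per-row classifications plus a tier tally.  Rows may be any
    objects with an ``acmg_criteria`` attribute or mappings with that key.
    Parse errors are re-raised naming the offending row.
    """
    results: list[ACMGClassification] = []
    tallies: Counter = Counter()
    for i, row in enumerate(rows):
        text = (
            row.get("acmg_criteria")
            if isinstance(row, dict)
            else getattr(row, "acmg_criteria", None)
        )
        try:
            crits = parse_criteria(text or "")
        except CriteriaParseError as exc:
            raise CriteriaParseError(f"row {i}: {exc}") from exc
        cls = combine_criteria(crits)
        results.append(cls)
        tallies[cls.tier] += 1
    return results, tallies
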