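"""Scoring and classification for a two-stage eye-phenotype modifier screen.

The screen crosses each deficiency (Df, a heterozygous chromosomal deletion)
to flies expressing one of two activated-Ras transgenes — a common-codon
(strong signalling) and a rare-codon (weak signalling) version — and grades
the rough-eye phenotype of the progeny into three ordinal categories:

    Mild = 1 (no discoloration or necrotic tissue),
    Moderate = 3 (discoloration, no necrotic tissue),
    Severe = 5 (discoloration and necrotic tissue).

The severity score of a cross is the category-weighted mean
``(1*n_mild + 3*n_moderate + 5*n_severe) / total`` and the fold-change score
of a Df is the severity of the Df cross divided by the severity of the
matching transgene-only control cross.  Animal lethality enters as the ratio
of eclosed flies between Df cross and control.  A transgene counts as
enhanced when the fold change exceeds the enhancer threshold OR eclosion
drops by the eclosion fold (lethality enhances by default; the orientation
is switchable), and as suppressed symmetrically.  A Df is then an enhancer
(both transgenes enhanced), a suppressor (both suppressed), differential
(exactly one transgene modified, or the two modified in opposite
directions), or not a modifier.  Dfs called modifier or differential in the
primary stage are re-evaluated against stricter secondary thresholds; a
call is confirmed when the secondary category matches the primary one.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

__all__ = [
    "ScreenError",
    "PhenotypeCounts",
    "CrossRecord",
    "ThresholdSet",
    "TransgeneEffect",
    "ModifierCall",
    "ScreenSummary",
    "ScreenResult",
    "PRIMARY_THRESHOLDS",
    "SECONDARY_THRESHOLDS",
    "TRANSGENES",
    "STAGES",
    "severity_score",
    "fold_change_score",
    "eclosion_ratio",
    "classify_transgene_effect",
    "classify_df",
    "run_screen",
]

logger = logging.getLogger(__name__)

TRANSGENES = ("common", "rare")
STAGES = ("primary", "secondary")

CATEGORY_NOT_MODIFIER = "not_modifier"
CATEGORY_ENHANCER = "enhancer"
CATEGORY_SUPPRESSOR = "suppressor"
CATEGORY_DIFFERENTIAL = "differential"
CATEGORY_NEEDS_REVIEW = "needs_review"


class ScreenError(ValueError):
    """Invalid screen records or thresholds."""


@dataclass(frozen=True)
class PhenotypeCounts:
    """Per-cross counts of mild / moderate / severe progeny."""

    n_mild: int
    n_moderate: int
    n_severe: int

    def __post_init__(self) -> None:
        if min(self.n_mild, self.n_moderate, self.n_severe) < 0:
            raise ScreenError("phenotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_mild + self.n_moderate + self.n_severe


@dataclass(frozen=True)
class CrossRecord:
    """One cross: a Df (or transgene-only control when ``df_id`` is empty),
    one transgene, one screen stage, with phenotype counts and the number of
    eclosed experimental-genotype flies.

    Scored flies are the eclosed experimental-genotype flies, so
    ``n_eclosed`` normally equals ``counts.total``; when omitted it defaults
    to the total.
    """

    df_id: str
    transgene: str
    stage: str
    counts: PhenotypeCounts
    n_eclosed: int | None = None

    def __post_init__(self) -> None:
        if self.transgene not in TRANSGENES:
            raise ScreenError(f"unknown transgene {self.transgene!r}")
        if self.stage not in STAGES:
            raise ScreenError(f"unknown stage {self.stage!r}")
        if self.n_eclosed is None:
            object.__setattr__(self, "n_eclosed", self.counts.total)
        elif self.n_eclosed < 0:
            raise ScreenError("n_eclosed must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.df_id == ""


@dataclass(frozen=True)
class ThresholdSet:
    """Stage-specific calling thresholds.

    ``lethality_enhances`` selects the orientation of the eclosion rule:
    when True (default) an eclosion ratio <= 1/eclosion_fold calls enhanced
    and >= eclosion_fold calls suppressed; when False the pairing is
    reversed.
    """

    enhancer_fc_min: float
    suppressor_fc_max: float
    eclosion_fold: float = 5.0
    stage: str = "primary"
    lethality_enhances: bool = True

    def __post_init__(self) -> None:
        if not (self.enhancer_fc_min > 1.0 > self.suppressor_fc_max > 0.0):
            raise ScreenError("need enhancer_fc_min > 1 > suppressor_fc_max > 0")
        if self.eclosion_fold <= 1.0:
            raise ScreenError("eclosion_fold must exceed 1")
        if self.stage not in STAGES:
            raise ScreenError(f"unknown stage {self.stage!r}")


PRIMARY_THRESHOLDS = ThresholdSet(1.35, 0.65, 5.0, "primary")
SECONDARY_THRESHOLDS = ThresholdSet(1.95, 0.50, 5.0, "secondary")


@dataclass(frozen=True)
class TransgeneEffect:
    """Evidence and call for one transgene of one Df at one stage."""

    df_id: str
    transgene: str
    stage: str
    severity_df: float
    severity_control: float
    fold_change: float
    eclosion_ratio: float
    call: str


@dataclass(frozen=True)
class ModifierCall:
    """Final per-Df classification with per-transgene evidence."""

    df_id: str
    category: str
    differential_detail: str | None = None
    stage_passed: str = "primary"  # primary | secondary_confirmed | secondary_failed
    flagged: bool = False  # e.g. secondary records without a primary hit


@dataclass(frozen=True)
class ScreenSummary:
    """Category tallies for one screen stage."""

    stage: str
    n_dfs_tested: int
    n_enhancer: int
    n_suppressor: int
    n_differential: int
    n_not_modifier: int
    n_needs_review: int = 0

    def percentages(self, ndigits: int = 1) -> dict[str, float]:
        if self.n_dfs_tested == 0:
            return {c: 0.0 for c in ("enhancer", "suppressor", "differential", "not_modifier")}
        return {
            "enhancer": round(100 * self.n_enhancer / self.n_dfs_tested, ndigits),
            "suppressor": round(100 * self.n_suppressor / self.n_dfs_tested, ndigits),
            "differential": round(100 * self.n_differential / self.n_dfs_tested, ndigits),
            "not_modifier": round(100 * self.n_not_modifier / self.n_dfs_tested, ndigits),
        }

    def percentages_int(self) -> dict[str, int]:
        return {k: round(v) for k, v in self.percentages(ndigits=6).items()}


@dataclass
class ScreenResult:
    calls: list[ModifierCall]
    effects: list[TransgeneEffect]
    primary_summary: ScreenSummary
    secondary_summary: ScreenSummary


# --- elementary scores ------------------------------------------------------


def severity_score(counts: PhenotypeCounts) -> float:
    """(1*mild + 3*moderate + 5*severe) / total; bounded in [1, 5]."""
    if counts.total == 0:
        raise ScreenError("no scored flies")
    return (
        counts.n_mild + 3 * counts.n_moderate + 5 * counts.n_severe
    ) / counts.total


def fold_change_score(
    df_counts: PhenotypeCounts, control_counts: PhenotypeCounts
) -> float:
    """Severity of the Df cross over severity of the control cross."""
    return severity_score(df_counts) / severity_score(control_counts)


def eclosion_ratio(
    df_eclosed: int, control_eclosed: int, normalization: float = 1.0
) -> float:
    """Eclosed flies in the Df cross relative to the control cross.

    ``normalization`` rescales the Df count for unequal cross sizes.
    """
    if control_eclosed <= 0:
        raise ScreenError("control cross has no eclosed flies")
    if df_eclosed < 0:
        raise ScreenError("df_eclosed must be non-negative")
    return normalization * df_eclosed / control_eclosed


# --- classification ---------------------------------------------------------


def classify_transgene_effect(fc: float, ecl: float, t: ThresholdSet) -> str:
    """Call one transgene: enhanced / suppressed / unmodified / ambiguous.

    ``fc`` may be NaN when the Df cross yielded no scorable flies, in which
    case only the eclosion rule applies (total lethality is itself the
    strongest enhancement signal under the default orientation).
    """
    if ecl < 0:
        raise ScreenError("eclosion ratio must be non-negative")
    fc_valid = not math.isnan(fc)
    if fc_valid and fc <= 0:
        raise ScreenError("fold change must be positive")

    fc_enh = fc_valid and fc >= t.enhancer_fc_min
    fc_sup = fc_valid and fc <= t.suppressor_fc_max
    if t.lethality_enhances:
        ecl_enh = ecl <= 1.0 / t.eclosion_fold
        ecl_sup = ecl >= t.eclosion_fold
    else:
        ecl_enh = ecl >= t.eclosion_fold
        ecl_sup = ecl <= 1.0 / t.eclosion_fold

    enhanced = fc_enh or ecl_enh
    suppressed = fc_sup or ecl_sup
    if enhanced and suppressed:
        return "ambiguous"
    if enhanced:
        return "enhanced"
    if suppressed:
        return "suppressed"
    return "unmodified"


def classify_df(common_call: str, rare_call: str) -> tuple[str, str | None]:
    """Combine the two per-transgene calls into a Df category.

    Returns ``(category, differential_detail)``; detail is present iff the
    category is differential.  A Df whose transgenes were modified in
    opposite directions is categorised differential with both directions
    preserved in the detail.  Either call ambiguous -> needs_review.
    """
    valid = ("enhanced", "suppressed", "unmodified", "ambiguous")
    for call in (common_call, rare_call):
        if call not in valid:
            raise ScreenError(f"unknown transgene call {call!r}")
    if "ambiguous" in (common_call, rare_call):
        return CATEGORY_NEEDS_REVIEW, None
    common_mod = common_call != "unmodified"
    rare_mod = rare_call != "unmodified"
    if not common_mod and not rare_mod:
        return CATEGORY_NOT_MODIFIER, None
    if common_mod and rare_mod:
        if common_call == rare_call:
            return (
                CATEGORY_ENHANCER if common_call == "enhanced" else CATEGORY_SUPPRESSOR,
                None,
            )
        return (
            CATEGORY_DIFFERENTIAL,
            f"mixed_common_{common_call}_rare_{rare_call}",
        )
    if common_mod:
        return CATEGORY_DIFFERENTIAL, f"common_only_{common_call}"
    return CATEGORY_DIFFERENTIAL, f"rare_only_{rare_call}"


# --- two-stage screen -------------------------------------------------------


def _aggregate(records: list[CrossRecord]) -> CrossRecord:
    """Collapse replicate rows for one (df, transgene, stage) key.

    Exact duplicate records are counted once (idempotent re-reads of the
    same table); distinct replicates are summed.
    """
    unique = list(dict.fromkeys(records))
    first = unique[0]
    if len(unique) == 1:
        return first
    counts = PhenotypeCounts(
        sum(r.counts.n_mild for r in unique),
        sum(r.counts.n_moderate for r in unique),
        sum(r.counts.n_severe for r in unique),
    )
    return CrossRecord(
        first.df_id,
        first.transgene,
        first.stage,
        counts,
        sum(r.n_eclosed for r in unique),
    )


def _stage_effects(
    by_key: dict[tuple[str, str, str], CrossRecord],
    df_ids: list[str],
    t: ThresholdSet,
) -> dict[str, dict[str, TransgeneEffect]]:
    """Per-Df, per-transgene effects for one stage."""
    stage = t.stage
    controls: dict[str, CrossRecord] = {}
    for tg in TRANSGENES:
        ctrl = by_key.get((stage, "", tg))
        if ctrl is None:
            raise ScreenError(f"missing {tg} control cross for stage {stage}")
        if ctrl.counts.total == 0:
            raise ScreenError(f"{stage} {tg} control cross has no scored flies")
        controls[tg] = ctrl

    effects: dict[str, dict[str, TransgeneEffect]] = {}
    for df_id in df_ids:
        per_tg: dict[str, TransgeneEffect] = {}
        for tg in TRANSGENES:
            rec = by_key.get((stage, df_id, tg))
            if rec is None:
                raise ScreenError(
                    f"Df {df_id!r} lacks a {tg} cross at stage {stage}"
                )
            ctrl = controls[tg]
            sev_ctrl = severity_score(ctrl.counts)
            if rec.counts.total:
                sev_df = severity_score(rec.counts)
                fc = sev_df / sev_ctrl
            else:
                sev_df = float("nan")
                fc = float("nan")
            ecl = eclosion_ratio(rec.n_eclosed, ctrl.n_eclosed)
            per_tg[tg] = TransgeneEffect(
                df_id, tg, stage, sev_df, sev_ctrl, fc, ecl,
                classify_transgene_effect(fc, ecl, t),
            )
        effects[df_id] = per_tg
    return effects


def run_screen(
    records: list[CrossRecord],
    primary_t: ThresholdSet = PRIMARY_THRESHOLDS,
    secondary_t: ThresholdSet = SECONDARY_THRESHOLDS,
) -> ScreenResult:
    """Classify every Df through the two-stage screen.

    Output is deterministic and independent of record order: records are
    grouped by (stage, df_id, transgene) and Dfs processed in sorted order.
    Only Dfs called modifier or differential at the primary stage are
    evaluated at the secondary stage; secondary records for other Dfs are
    flagged and counted in a single warning.
    """
    grouped: dict[tuple[str, str, str], list[CrossRecord]] = defaultdict(list)
    for rec in records:
        grouped[(rec.stage, rec.df_id, rec.transgene)].append(rec)
    by_key = {k: _aggregate(v) for k, v in grouped.items()}

    primary_dfs = sorted(
        {df for (stage, df, _) in by_key if stage == "primary" and df}
    )
    secondary_dfs = {
        df for (stage, df, _) in by_key if stage == "secondary" and df
    }

    primary_effects = _stage_effects(by_key, primary_dfs, primary_t)
    effects: list[TransgeneEffect] = []
    primary_cat: dict[str, tuple[str, str | None]] = {}
    for df_id in primary_dfs:
        per_tg = primary_effects[df_id]
        effects.extend(per_tg[tg] for tg in TRANSGENES)
        primary_cat[df_id] = classify_df(
            per_tg["common"].call, per_tg["rare"].call
        )

    hits = [
        df
        for df in primary_dfs
        if primary_cat[df][0]
        in (CATEGORY_ENHANCER, CATEGORY_SUPPRESSOR, CATEGORY_DIFFERENTIAL)
    ]
    retested = [df for df in hits if df in secondary_dfs]
    # secondary records for primary non-hits are simply not evaluated; a Df
    # with no primary records at all is processed at secondary but flagged
    unexpected = sorted(secondary_dfs - set(primary_dfs))
    if unexpected:
        logger.warning(
            "%d Dfs have secondary records but no primary records; flagged",
            len(unexpected),
        )

    secondary_cat: dict[str, tuple[str, str | None]] = {}
    if retested or unexpected:
        secondary_effects = _stage_effects(
            by_key, sorted(set(retested) | set(unexpected)), secondary_t
        )
        for df_id, per_tg in sorted(secondary_effects.items()):
            effects.extend(per_tg[tg] for tg in TRANSGENES)
            secondary_cat[df_id] = classify_df(
                per_tg["common"].call, per_tg["rare"].call
            )

    calls: list[ModifierCall] = []
    for df_id in primary_dfs:
        category, detail = primary_cat[df_id]
        if df_id in retested:
            sec_category, sec_detail = secondary_cat[df_id]
            if sec_category == category:
                stage_passed = "secondary_confirmed"
                if category == CATEGORY_DIFFERENTIAL:
                    detail = sec_detail
            else:
                stage_passed = "secondary_failed"
        else:
            stage_passed = "primary"
        calls.append(
            ModifierCall(df_id, category, detail, stage_passed, flagged=False)
        )
    for df_id in unexpected:
        category, detail = secondary_cat[df_id]
        calls.append(
            ModifierCall(df_id, category, detail, "secondary_failed", flagged=True)
        )

    primary_summary = _summarize("primary", [primary_cat[df][0] for df in primary_dfs])
    confirmed = [
        c.category for c in calls
        if c.stage_passed == "secondary_confirmed" and not c.flagged
    ]
    secondary_summary = ScreenSummary(
        stage="secondary",
        n_dfs_tested=len(retested),
        n_enhancer=confirmed.count(CATEGORY_ENHANCER),
        n_suppressor=confirmed.count(CATEGORY_SUPPRESSOR),
        n_differential=confirmed.count(CATEGORY_DIFFERENTIAL),
        n_not_modifier=len(retested) - len(confirmed),
    )
    return ScreenResult(calls, effects, primary_summary, secondary_summary)


def _summarize(stage: str, categories: list[str]) -> ScreenSummary:
    return ScreenSummary(
        stage=stage,
        n_dfs_tested=len(categories),
        n_enhancer=categories.count(CATEGORY_ENHANCER),
        n_suppressor=categories.count(CATEGORY_SUPPRESSOR),
        n_differential=categories.count(CATEGORY_DIFFERENTIAL),
        n_not_modifier=categories.count(CATEGORY_NOT_MODIFIER),
        n_needs_review=categories.count(CATEGORY_NEEDS_REVIEW),
    )
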