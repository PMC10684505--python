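"""Synthetic data generators with known ground truth.

Two generators drive the whole project:

* :func:`generate_corpus` — social-media corpora with planted topics.
  Each topic owns a keyword lexicon; posts mix topic words with a shared
  filler vocabulary (30% of tokens by default) so clusters are separable
  but not trivially disjoint.  Per-topic rates control how many posts
  mention the target keyword ("alcohol") and, among those, how many
  carry a reduction-lexicon phrase.

* :func:`generate_cohort` — remote-survey cohorts.  Daily drink counts
  follow a Poisson log-linear model (intercept + weekend + group +
  group x weekend + personal random intercept); daily binge indicators
  follow the analogous logistic model; AUDIT/BAES/drinks-per-episode
  responses are produced by drawing a target scale score and
  distributing it across items within each item's range.

Both generators are fully deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Post

__all__ = [
    "SpecificationError",
    "TopicSpec",
    "CorpusSpec",
    "CohortSpec",
    "GroupShift",
    "CohortTable",
    "generate_corpus",
    "generate_cohort",
    "disjoint_topics",
    "tlfb_long",
    "write_cohort_csvs",
    "GROUPS",
]

GROUPS = ("control", "semaglutide", "tirzepatide")


class SpecificationError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class TopicSpec:
    name: str
    weight: float
    lexicon: tuple[str, ...]
    lexicon_probs: tuple[float, ...] | None = None  # uniform if None
    mean_length: int = 60  # mean tokens per post


@dataclass
class CorpusSpec:
    n_posts: int
    n_users: int
    date_range: tuple[date, date]
    topics: list[TopicSpec]
    alcohol_rate_by_topic: dict[str, float]
    reduction_rate: float
    seed: int | None = None
    filler_rate: float = 0.3
    filler_vocab_size: int = 100
    growth_weighted: bool = False  # exponential late-surge timestamps

    def validate(self) -> None:
        if self.seed is None:
            raise SpecificationError("seed is mandatory (reproducibility)")
        if self.n_posts < 1 or self.n_users < 1:
            raise SpecificationError("n_posts and n_users must be positive")
        w = sum(t.weight for t in self.topics)
        if abs(w - 1.0) > 1e-12:
            raise SpecificationError(f"topic weights must sum to 1, got {w}")
        if self.date_range[0] > self.date_range[1]:
            raise SpecificationError("date_range must be ordered")
        rates = list(self.alcohol_rate_by_topic.values()) + [self.reduction_rate]
        if any(not 0 <= r <= 1 for r in rates):
            raise SpecificationError("all rates must lie in [0, 1]")
        names = {t.name for t in self.topics}
        unknown = set(self.alcohol_rate_by_topic) - names
        if unknown:
            raise SpecificationError(f"alcohol rates for unknown topics: {unknown}")


def disjoint_topics(
    n_topics: int,
    lexicon_size: int = 50,
    mean_length: int = 60,
    weights: Sequence[float] | None = None,
) -> list[TopicSpec]:
    """Equal-weight topics with disjoint synthetic lexicons."""
    if weights is None:
        weights = [1.0 / n_topics] * n_topics
    return [
        TopicSpec(
            name=f"topic{t}",
            weight=float(weights[t]),
            lexicon=tuple(f"t{t}word{w:03d}" for w in range(lexicon_size)),
            mean_length=mean_length,
        )
        for t in range(n_topics)
    ]


# phrases planted in keyword posts; the reduction templates each contain a
# reduction-lexicon phrase, the neutral ones contain none
_REDUCTION_TEMPLATES = (
    ("stopped", "drinking", "alcohol"),
    ("reduced", "alcohol", "intake"),
    ("alcohol", "makes", "me", "sick"),
    ("nausea", "after", "alcohol"),
    ("don't", "want", "alcohol", "anymore"),
    ("alcohol", "craving", "gone"),
    ("cutback", "on", "alcohol"),
    ("low", "tolerance", "for", "alcohol"),
)
_NEUTRAL_TEMPLATES = (
    ("enjoy", "alcohol", "on", "weekends"),
    ("alcohol", "tastes", "same", "as", "always"),
    ("still", "drink", "alcohol", "sometimes"),
)

_SUBREDDITS = ("r_glp1", "r_meds", "r_weightloss", "r_diabetes", "r_health")


def generate_corpus(spec: CorpusSpec) -> tuple[list[Post], pd.DataFrame]:
    """Generate raw posts plus a per-post ground-truth table.

    Returns ``(posts, truth)`` where ``truth`` has columns ``id``,
    ``topic``, ``is_alcohol`` and ``is_reduction``; every alcohol-flagged
    post contains the literal token ``alcohol``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([t.weight for t in spec.topics])
    filler = [f"filler{i:03d}" for i in range(spec.filler_vocab_size)]
    t0 = datetime.combine(spec.date_range[0], datetime.min.time(), tzinfo=timezone.utc)
    t1 = datetime.combine(spec.date_range[1], datetime.min.time(), tzinfo=timezone.utc)
    span = max((t1 - t0).total_seconds(), 1.0)

    topic_idx = rng.choice(len(spec.topics), size=spec.n_posts, p=weights)
    posts: list[Post] = []
    truth_rows = []
    for i in range(spec.n_posts):
        topic = spec.topics[topic_idx[i]]
        n_tokens = max(8, int(rng.poisson(topic.mean_length)))
        from_filler = rng.random(n_tokens) < spec.filler_rate
        lex_probs = topic.lexicon_probs
        toks = [
            (
                filler[rng.integers(len(filler))]
                if use_f
                else topic.lexicon[rng.choice(len(topic.lexicon), p=lex_probs)]
            )
            for use_f in from_filler
        ]
        is_alcohol = bool(rng.random() < spec.alcohol_rate_by_topic.get(topic.name, 0.0))
        is_reduction = False
        if is_alcohol:
            is_reduction = bool(rng.random() < spec.reduction_rate)
            pool = _REDUCTION_TEMPLATES if is_reduction else _NEUTRAL_TEMPLATES
            phrase = pool[rng.integers(len(pool))]
            at = int(rng.integers(0, len(toks) + 1))
            toks = toks[:at] + list(phrase) + toks[at:]

        if spec.growth_weighted:
            frac = rng.beta(5.0, 1.0)  # mass concentrated late in the range
        else:
            frac = rng.random()
        ts = t0 + timedelta(seconds=float(frac) * span)
        n_title = min(6, len(toks))
        posts.append(
            Post(
                id=f"p{i:06d}",
                user=f"user{rng.integers(spec.n_users):05d}",
                subreddit=_SUBREDDITS[rng.integers(len(_SUBREDDITS))],
                timestamp=ts,
                title=" ".join(toks[:n_title]),
                body=" ".join(toks[n_title:]),
            )
        )
        truth_rows.append(
            {
                "id": posts[-1].id,
                "topic": topic.name,
                "is_alcohol": is_alcohol,
                "is_reduction": is_reduction,
            }
        )
    return posts, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupShift:
    """Pre-period score distribution and the post-period shift of its mean."""

    pre_mean: float
    pre_sd: float
    post_shift: float = 0.0


def _default_audit() -> dict[str, GroupShift]:
    return {
        "control": GroupShift(14.0, 7.0, 0.0),
        "semaglutide": GroupShift(15.5, 7.0, -6.63),
        "tirzepatide": GroupShift(14.0, 7.0, -6.63),
    }


def _default_baes() -> dict[str, dict[str, GroupShift]]:
    return {
        "stimulative": {
            "control": GroupShift(35.0, 12.0, 0.0),
            "semaglutide": GroupShift(35.0, 12.0, -9.06),
            "tirzepatide": GroupShift(35.0, 12.0, -9.06),
        },
        "sedative": {
            "control": GroupShift(35.0, 12.0, 0.0),
            "semaglutide": GroupShift(35.0, 12.0, -9.69),
            "tirzepatide": GroupShift(35.0, 12.0, -9.69),
        },
    }


def _default_episode() -> dict[str, GroupShift]:
    return {
        "control": GroupShift(6.0, 2.5, 0.0),
        "semaglutide": GroupShift(6.0, 2.5, -2.34),
        "tirzepatide": GroupShift(6.0, 2.5, -2.34),
    }


@dataclass
class CohortSpec:
    """Generating parameters for a remote-survey cohort.

    ``coef_drinks`` and ``coef_binge`` are (intercept, weekend,
    (semaglutide, tirzepatide), (semaglutide x weekend, tirzepatide x
    weekend)) on the log / logit scale.  The defaults plant the
    coefficient values reported for the study cohort; the binge and
    drinks intercepts and the random-intercept SD are free choices (see
    the methods note).
    """

    n_per_group: tuple[int, int, int] = (47, 56, 50)  # control, sema, tirz
    coef_drinks: dict = field(
        default_factory=lambda: {
            "intercept": float(np.log(1.5)),
            "weekend": 0.85,
            "group": (-1.31, -1.54),
            "group_x_weekend": (-0.17, -0.45),
        }
    )
    coef_binge: dict = field(
        default_factory=lambda: {
            "intercept": -1.5,
            "weekend": 1.4178,
            "group": (-2.0517, -3.7920),
            "group_x_weekend": (0.0, 0.0),
        }
    )
    audit_effects: dict = field(default_factory=_default_audit)
    baes_effects: dict = field(default_factory=_default_baes)
    episode_effects: dict = field(default_factory=_default_episode)
    random_intercept_sd: float = 0.5
    sex_ratio: float = 29 / 153  # probability male
    diary_start: date = date(2023, 8, 1)
    n_days: int = 30
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise SpecificationError("seed is mandatory (reproducibility)")
        if any(n < 1 for n in self.n_per_group):
            raise SpecificationError("group sizes must be >= 1")
        if self.random_intercept_sd < 0:
            raise SpecificationError("random_intercept_sd must be >= 0")
        sds = [g.pre_sd for g in self.audit_effects.values()]
        sds += [g.pre_sd for sub in self.baes_effects.values() for g in sub.values()]
        sds += [g.pre_sd for g in self.episode_effects.values()]
        if any(s < 0 for s in sds):
            raise SpecificationError("score SDs must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise SpecificationError("sex_ratio must lie in [0, 1]")


@dataclass
class CohortTable:
    participants: pd.DataFrame
    tlfb: pd.DataFrame  # one row per participant-day
    instruments: pd.DataFrame  # one row per participant-timepoint


def _alloc_items(rng: np.random.Generator, total: int, caps: np.ndarray) -> np.ndarray:
    """Distribute ``total`` points over items with per-item caps."""
    vals = np.zeros(len(caps), dtype=int)
    remaining = int(total)
    while remaining > 0:
        open_idx = np.flatnonzero(vals < caps)
        pick = int(rng.choice(open_idx))
        vals[pick] += 1
        remaining -= 1
    return vals


def _audit_items(rng: np.random.Generator, total: int) -> np.ndarray:
    """AUDIT option indices whose scored total equals ``total`` (0..40).

    Items 9-10 score in steps of 2, so their point share is drawn first
    (an even amount consistent with the 0..32 capacity of items 1-8) and
    the remainder spread over items 1-8.
    """
    total = int(np.clip(total, 0, 40))
    e_min = max(0, total - 32)
    e_min += e_min % 2
    e_max = min(8, total)
    e_max -= e_max % 2
    e_sum = int(rng.choice(np.arange(e_min, e_max + 1, 2)))
    pairs = [(a, b) for a in (0, 2, 4) for b in (0, 2, 4) if a + b == e_sum]
    e9, e10 = pairs[rng.integers(len(pairs))]
    first8 = _alloc_items(rng, total - e_sum, np.full(8, 4))
    return np.concatenate([first8, [e9 // 2, e10 // 2]])


def _baes_items(rng: np.random.Generator, stim_total: int, sed_total: int) -> np.ndarray:
    stim = _alloc_items(rng, int(np.clip(stim_total, 0, 70)), np.full(7, 10))
    sed = _alloc_items(rng, int(np.clip(sed_total, 0, 70)), np.full(7, 10))
    return np.concatenate([stim, sed])


_RACES = ("White/Caucasian", "Black/African American", "Asian", "Other")
_RACE_P = (0.89, 0.06, 0.01, 0.04)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Simulate a survey cohort from the generating models in the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(spec.diary_start, periods=spec.n_days)
    is_weekend = dates.dayofweek.isin([4, 5, 6]).astype(float)  # Fri/Sat/Sun

    part_rows, tlfb_rows, inst_rows = [], [], []
    pidx = 0
    for g_i, (group, n) in enumerate(zip(GROUPS, spec.n_per_group)):
        for _ in range(n):
            pid = f"P{pidx:03d}"
            pidx += 1
            male = rng.random() < spec.sex_ratio
            dose = None
            if group == "semaglutide":
                dose = float(np.round(np.clip(rng.normal(1.0, 0.5), 0.25, 2.4), 2))
            elif group == "tirzepatide":
                dose = float(np.round(np.clip(rng.normal(7.5, 3.0), 0.5, 15.0), 1))
            part_rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "sex": "male" if male else "female",
                    "age": float(np.round(np.clip(rng.normal(41.0, 10.0), 21, 75), 1)),
                    "education": float(np.round(np.clip(rng.normal(15.3, 4.5), 8, 25), 1)),
                    "bmi": float(np.round(np.clip(rng.normal(35.6, 6.4), 30, 60), 1)),
                    "ethnicity": (
                        "not Hispanic or Latino" if rng.random() < 0.93 else "Hispanic or Latino"
                    ),
                    "race": _RACES[rng.choice(len(_RACES), p=_RACE_P)],
                    "dose_mg": dose,
                }
            )

            # daily diary: Poisson drinks and Bernoulli binge indicators
            cd, cb = spec.coef_drinks, spec.coef_binge
            g_drinks = cd["group"][g_i - 1] if g_i > 0 else 0.0
            g_binge = cb["group"][g_i - 1] if g_i > 0 else 0.0
            gxw_drinks = cd["group_x_weekend"][g_i - 1] if g_i > 0 else 0.0
            gxw_binge = cb["group_x_weekend"][g_i - 1] if g_i > 0 else 0.0
            u_drinks = rng.normal(0.0, spec.random_intercept_sd)
            u_binge = rng.normal(0.0, spec.random_intercept_sd)
            eta_d = (
                cd["intercept"] + g_drinks + u_drinks
                + (cd["weekend"] + gxw_drinks) * is_weekend
            )
            eta_b = (
                cb["intercept"] + g_binge + u_binge
                + (cb["weekend"] + gxw_binge) * is_weekend
            )
            drinks = rng.poisson(np.exp(eta_d))
            binge = (rng.random(spec.n_days) < 1.0 / (1.0 + np.exp(-eta_b))).astype(int)
            for d, w, dr, bg in zip(dates, is_weekend, drinks, binge):
                tlfb_rows.append(
                    {
                        "participant": pid,
                        "date": d.date().isoformat(),
                        "drinks": int(dr),
                        "is_weekend": bool(w),
                        "binge": int(bg),
                    }
                )

            # instruments: control reports the current timepoint only
            audit = spec.audit_effects[group]
            stim = spec.baes_effects["stimulative"][group]
            sed = spec.baes_effects["sedative"][group]
            epis = spec.episode_effects[group]
            audit_pre = float(np.clip(rng.normal(audit.pre_mean, audit.pre_sd), 0, 40))
            stim_pre = float(np.clip(rng.normal(stim.pre_mean, stim.pre_sd), 0, 70))
            sed_pre = float(np.clip(rng.normal(sed.pre_mean, sed.pre_sd), 0, 70))
            ep_pre = float(np.clip(rng.normal(epis.pre_mean, epis.pre_sd), 0, 30))
            timepoints = ("current",) if group == "control" else ("pre", "current")
            for tp in timepoints:
                if tp == "pre":
                    a_t, s_t, d_t, e_t = audit_pre, stim_pre, sed_pre, ep_pre
                else:
                    a_t = np.clip(audit_pre + audit.post_shift + rng.normal(0, 2.0), 0, 40)
                    s_t = np.clip(stim_pre + stim.post_shift + rng.normal(0, 4.0), 0, 70)
                    d_t = np.clip(sed_pre + sed.post_shift + rng.normal(0, 4.0), 0, 70)
                    e_t = np.clip(ep_pre + epis.post_shift + rng.normal(0, 1.0), 0, 30)
                row = {"participant": pid, "timepoint": tp}
                for k, v in enumerate(_audit_items(rng, round(a_t)), start=1):
                    row[f"audit_{k}"] = int(v)
                for k, v in enumerate(_baes_items(rng, round(s_t), round(d_t)), start=1):
                    row[f"baes_{k}"] = int(v)
                row["drinks_per_episode"] = int(round(e_t))
                inst_rows.append(row)

    return CohortTable(
        participants=pd.DataFrame(part_rows),
        tlfb=pd.DataFrame(tlfb_rows),
        instruments=pd.DataFrame(inst_rows),
    )


def tlfb_long(cohort: CohortTable) -> pd.DataFrame:
    """Long-format modelling frame: one row per participant-day with the
    weekend indicator as the within-subject time variable."""
    df = cohort.tlfb.merge(
        cohort.participants[["participant", "group", "sex"]], on="participant"
    )
    df["time"] = df["is_weekend"].astype(int)
    df["group"] = pd.Categorical(df["group"], categories=list(GROUPS))
    return df[["participant", "group", "sex", "date", "time", "drinks", "binge"]]


def write_cohort_csvs(cohort: CohortTable, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(outdir / "participants.csv", index=False)
    cohort.tlfb.to_csv(outdir / "tlfb_daily.csv", index=False)
    cohort.instruments.to_csv(outdir / "instruments.csv", index=False)
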