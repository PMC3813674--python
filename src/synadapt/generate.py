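"""Experiment designs and synthetic self-paced-reading data.

Two designs are built here.  The first interleaves 36 critical items
(18 reduced-relative, 18 main-verb; half of each temporarily ambiguous,
rotated over four counterbalancing lists) with 50 fillers, so that half of
all ambiguous trials resolve to the a-priori rare RC structure.  The second
is a three-block, two-group design: an RC-First group reads 16 RCs in
Block 1 while a Filler-First group reads 16 fillers, and both groups then
read identical Blocks 2 (10 RCs + 20 fillers) and 3 (10 MVs + 15 fillers).
Block structure is implicit -- nothing in the trial stream marks it.

Synthetic word-by-word reading times are generated from the belief model and
link parameters: each subject carries a belief state updated after every
critical sentence, and the disambiguating region of ambiguous trials costs
``rt_slope`` ms per bit of the current surprisal of the resolved structure.
Word lengths and filler lengths are properties of the stimuli and therefore
fixed per counterbalancing list; only subject-level parameters, trial noise
and outlier contamination vary across subjects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .belief import BeliefState, PriorConfig, make_prior
from .rt_link import LinkParams

#: Region scheme of a critical sentence: region name and word count.
REGION_SCHEME: tuple[tuple[str, int], ...] = (
    ("preamble", 3),
    ("ambiguous_region", 4),
    ("disambiguating_region", 3),
    ("final_word", 1),
)

#: Exact column order of the trial CSV dialect.
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "list_id",
    "group",
    "block",
    "stimulus_order",
    "item_order",
    "kind",
    "structure",
    "ambiguity",
    "region",
    "word_index",
    "word_length",
    "rt_raw",
)

_WORD_LENGTHS = np.arange(2, 13)
_WORD_LENGTH_WEIGHTS = np.array([8, 10, 12, 10, 8, 6, 4, 3, 2, 1.5, 1])
_WORD_LENGTH_PROBS = _WORD_LENGTH_WEIGHTS / _WORD_LENGTH_WEIGHTS.sum()

_EXP1_CONDITIONS = (
    ("MV", "ambiguous"),
    ("MV", "unambiguous"),
    ("RC", "ambiguous"),
    ("RC", "unambiguous"),
)


class TrialParseError(ValueError):
    """Raised when a trial CSV does not conform to the dialect."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered stimulus streams for every counterbalancing list.

    ``trials`` is one row per list x stimulus; ``words`` expands each
    stimulus to its words (region, word index, word length).  Subjects are
    assigned to lists round-robin.
    """

    experiment: str
    group: str | None
    n_subjects: int
    n_lists: int
    seed: int
    trials: pd.DataFrame
    words: pd.DataFrame

    def list_for_subject(self, subject_idx: int) -> int:
        return subject_idx % self.n_lists

    def evidence(self, list_id: int = 0) -> pd.DataFrame:
        """Critical trials of one list, in presentation order."""
        t = self.trials
        crit = t[(t["list_id"] == list_id) & (t["kind"] == "critical")]
        crit = crit.sort_values("stimulus_order")
        return crit[["structure", "block"]].reset_index(drop=True)


def exp1_evidence() -> pd.DataFrame:
    """Canonical alternating 36-item evidence sequence for the first design.

    Used for the idealized predicted-surprisal trajectories: 18 RC and 18 MV
    critical observations in strict alternation (RC first), matching the
    design's balanced statistics without the sampling noise of a particular
    shuffle.
    """
    structures = ["RC", "MV"] * 18
    return pd.DataFrame({"structure": structures, "block": pd.NA})


def exp2_evidence(group: str, fillers_as_other: bool = False) -> pd.DataFrame:
    """Canonical block-ordered evidence sequence for the two-group design.

    Fillers carry no MV/RC evidence by default; set ``fillers_as_other`` to
    count the Filler-First group's Block-1 fillers as OTHER observations.
    """
    _check_group(group)
    rows: list[tuple[str, int]] = []
    if group == "RC_First":
        rows += [("RC", 1)] * 16
    elif fillers_as_other:
        rows += [("OTHER", 1)] * 16
    rows += [("RC", 2)] * 10
    rows += [("MV", 3)] * 10
    return pd.DataFrame(rows, columns=["structure", "block"])


def _check_group(group: str) -> None:
    if group not in ("RC_First", "Filler_First"):
        raise ValueError(
            f"unknown group {group!r}; expected 'RC_First' or 'Filler_First'"
        )


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_WORD_LENGTHS, size=n, p=_WORD_LENGTH_PROBS)


def _expand_words(trials: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Expand trial rows to word rows with regions and seeded word lengths."""
    rows = []
    for tr in trials.itertuples(index=False):
        if tr.kind == "critical":
            regions: list[str] = []
            for name, count in REGION_SCHEME:
                regions += [name] * count
        else:
            regions = ["filler_body"] * int(rng.integers(8, 15))
        n = len(regions)
        lengths = _draw_lengths(rng, n)
        for w, (region, length) in enumerate(zip(regions, lengths), start=1):
            rows.append(
                tr._asdict()
                | {"region": region, "word_index": w, "word_length": int(length)}
            )
    return pd.DataFrame(rows)


def _finalize_design(
    experiment: str,
    group: str | None,
    n_subjects: int,
    n_lists: int,
    seed: int,
    per_list_trials: list[pd.DataFrame],
) -> ExperimentDesign:
    trials = pd.concat(per_list_trials, ignore_index=True)
    word_frames = []
    for list_id, tframe in enumerate(per_list_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + list_id]))
        word_frames.append(_expand_words(tframe, rng))
    words = pd.concat(word_frames, ignore_index=True)
    trials["item_order"] = trials["item_order"].astype("Int64")
    trials["block"] = trials["block"].astype("Int64")
    words["item_order"] = words["item_order"].astype("Int64")
    words["block"] = words["block"].astype("Int64")
    return ExperimentDesign(
        experiment=experiment,
        group=group,
        n_subjects=n_subjects,
        n_lists=n_lists,
        seed=seed,
        trials=trials,
        words=words,
    )


def build_design_exp1(n_subjects: int = 72, seed: int = 0) -> ExperimentDesign:
    """36 critical items plus 50 fillers in seeded pseudo-random order.

    Items come in quadruplet versions (MV/RC x ambiguous/unambiguous)
    rotated over 4 Latin-square lists, giving each subject 18 RC and 18 MV
    items with half of each ambiguous -- so half of all ambiguous trials
    resolve toward the RC structure.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    n_lists = 4
    # One presentation order shared by all lists, with the condition of each
    # item rotated across lists: every stimulus position hosts each condition
    # in exactly one list, so position effects cancel across lists.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    item_ids = list(range(36)) + [-1] * 50  # -1 marks fillers
    order = [item_ids[i] for i in rng.permutation(len(item_ids))]
    per_list = []
    for list_id in range(n_lists):
        rows = []
        for item in order:
            if item >= 0:
                structure, ambiguity = _EXP1_CONDITIONS[(item + list_id) % 4]
                rows.append(
                    {
                        "list_id": list_id,
                        "group": None,
                        "block": None,
                        "kind": "critical",
                        "structure": structure,
                        "ambiguity": ambiguity,
                    }
                )
            else:
                rows.append(
                    {
                        "list_id": list_id,
                        "group": None,
                        "block": None,
                        "kind": "filler",
                        "structure": None,
                        "ambiguity": None,
                    }
                )
        frame = pd.DataFrame(rows)
        frame["stimulus_order"] = np.arange(1, len(frame) + 1)
        frame["item_order"] = _item_orders(frame["kind"])
        per_list.append(frame)
    return _finalize_design("exp1", None, n_subjects, n_lists, seed, per_list)


def _item_orders(kind: pd.Series) -> pd.Series:
    is_crit = (kind == "critical").to_numpy()
    orders = np.where(is_crit, np.cumsum(is_crit), 0)
    return pd.Series(orders).astype("Int64").mask(~is_crit, pd.NA)


def _exp2_block(
    list_id: int,
    block: int,
    structure: str | None,
    n_critical: int,
    n_ambiguous: int,
    n_fillers: int,
    group: str,
) -> pd.DataFrame:
    rows = []
    for j in range(n_critical):
        # counterbalance ambiguity across the two lists
        ambiguous = (j + list_id) % 2 < 1 if n_ambiguous * 2 == n_critical else None
        rows.append(
            {
                "list_id": list_id,
                "group": group,
                "block": block,
                "kind": "critical",
                "structure": structure,
                "ambiguity": "ambiguous" if ambiguous else "unambiguous",
            }
        )
    rows += [
        {
            "list_id": list_id,
            "group": group,
            "block": block,
            "kind": "filler",
            "structure": None,
            "ambiguity": None,
        }
        for _ in range(n_fillers)
    ]
    return pd.DataFrame(rows)


def build_design_exp2(
    group: str, n_subjects: int = 40, seed: int = 0
) -> ExperimentDesign:
    """Three-block two-group design: 71 stimuli per subject.

    RC-First: Block 1 = 16 RCs (8 ambiguous); Filler-First: Block 1 = 16
    fillers.  Both groups: Block 2 = 10 RCs (5 ambiguous) + 20 fillers,
    Block 3 = 10 MVs (5 ambiguous) + 15 fillers.  Ambiguity is
    counterbalanced over two lists per group; trials are shuffled within
    block and blocks carry no overt marker in the stimulus stream.
    """
    _check_group(group)
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    n_lists = 2
    # Shared within-block shuffle across the two lists; only the ambiguity
    # assignment rotates, so ambiguous and unambiguous versions of an item
    # occupy the same stimulus position in both lists.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    block_perms = {}
    per_list = []
    for list_id in range(n_lists):
        if group == "RC_First":
            b1 = _exp2_block(list_id, 1, "RC", 16, 8, 0, group)
        else:
            b1 = _exp2_block(list_id, 1, None, 0, 0, 16, group)
        b2 = _exp2_block(list_id, 2, "RC", 10, 5, 20, group)
        b3 = _exp2_block(list_id, 3, "MV", 10, 5, 15, group)
        shuffled = []
        for block_no, b in enumerate((b1, b2, b3), start=1):
            if block_no not in block_perms:
                block_perms[block_no] = rng.permutation(len(b))
            shuffled.append(b.iloc[block_perms[block_no]].reset_index(drop=True))
        frame = pd.concat(shuffled, ignore_index=True)
        frame["stimulus_order"] = np.arange(1, len(frame) + 1)
        frame["item_order"] = _item_orders(frame["kind"])
        per_list.append(frame)
    return _finalize_design("exp2", group, n_subjects, n_lists, seed, per_list)


# ---------------------------------------------------------------------------
# reading-time generation
# ---------------------------------------------------------------------------


def _list_costs(
    design: ExperimentDesign,
    list_id: int,
    prior: PriorConfig,
    link: LinkParams,
    fixed_ambiguity_cost: float | None = None,
) -> pd.DataFrame:
    """Disambiguating-region cost of every trial in one list's stream.

    The belief state evolves deterministically along a list's critical-item
    sequence (it is updated at sentence offset), so the per-trial cost --
    ``rt_slope`` x current surprisal of the resolved structure for ambiguous
    trials, a constant offset for unambiguous ones -- is a property of the
    list, shared by all its subjects.
    """
    trials = design.trials[design.trials["list_id"] == list_id].sort_values(
        "stimulus_order"
    )
    state = make_prior(prior)
    costs = []
    for tr in trials.itertuples(index=False):
        cost = 0.0
        if tr.kind == "critical":
            if tr.ambiguity == "ambiguous":
                if fixed_ambiguity_cost is not None:
                    cost = fixed_ambiguity_cost
                else:
                    cost = link.rt_slope * -np.log2(
                        state.predictive_prob(tr.structure)
                    )
            else:
                cost = link.unambig_offset
            state = state.observe(tr.structure)
        costs.append(cost)
    return pd.DataFrame(
        {"stimulus_order": trials["stimulus_order"].to_numpy(), "region_cost": costs}
    )


def generate_dataset(
    design: ExperimentDesign,
    prior: PriorConfig | None = None,
    link: LinkParams | None = None,
    seed: int = 0,
    outlier_fraction: float = 0.005,
    region_effects: bool = True,
    fixed_ambiguity_cost: float | None = None,
) -> pd.DataFrame:
    """Generate a word-by-word reading-time dataset for a design.

    Per subject: a baseline deviation and a word-length slope are drawn,
    and every word's RT is baseline + length sensitivity x word length +
    task adaptation x log stimulus order + region cost + Gaussian noise
    (truncated at 1 ms).  A small fraction of words is replaced by
    out-of-range RTs to exercise the exclusion rules.  Subject-level
    randomness uses one spawned stream per subject, so enlarging
    ``n_subjects`` never perturbs earlier subjects' data.

    Set ``region_effects=False`` to disable all disambiguating-region and
    spillover costs (a null generator for calibration checks), or
    ``fixed_ambiguity_cost`` to inject a constant garden-path cost
    irrespective of the belief model (for parameter-recovery oracles).
    """
    prior = prior or PriorConfig()
    link = link or LinkParams()
    if not 0 <= outlier_fraction < 1:
        raise ValueError(f"outlier_fraction must be in [0, 1), got {outlier_fraction}")

    templates = {}
    for list_id in range(design.n_lists):
        words = design.words[design.words["list_id"] == list_id].copy()
        words = words.sort_values(["stimulus_order", "word_index"]).reset_index(
            drop=True
        )
        if region_effects:
            costs = _list_costs(design, list_id, prior, link, fixed_ambiguity_cost)
            words = words.merge(costs, on="stimulus_order", how="left")
            cost = words["region_cost"].fillna(0.0).to_numpy()
            effect = np.where(
                words["region"] == "disambiguating_region", cost, 0.0
            ) + np.where(words["region"] == "final_word", link.spillover_frac * cost, 0.0)
            words = words.drop(columns="region_cost")
        else:
            effect = np.zeros(len(words))
        words["_effect"] = effect
        templates[list_id] = words

    root = np.random.SeedSequence(seed)
    children = root.spawn(design.n_subjects)
    frames = []
    for s in range(design.n_subjects):
        rng = np.random.default_rng(children[s])
        list_id = design.list_for_subject(s)
        tpl = templates[list_id]
        n = len(tpl)
        subj_int = link.rt_intercept + rng.normal(0.0, link.subj_intercept_sd)
        subj_slope = rng.normal(
            link.subj_length_slope_mean, link.subj_length_slope_sd
        )
        rt = (
            subj_int
            + subj_slope * tpl["word_length"].to_numpy()
            + link.task_adapt_coef * np.log(tpl["stimulus_order"].to_numpy())
            + tpl["_effect"].to_numpy()
            + rng.normal(0.0, link.noise_sd, n)
        )
        rt = np.maximum(rt, 1.0)
        if outlier_fraction > 0:
            mask = rng.random(n) < outlier_fraction
            n_out = int(mask.sum())
            if n_out:
                low = rng.uniform(20.0, 95.0, n_out)
                high = rng.uniform(2100.0, 3500.0, n_out)
                rt[mask] = np.where(rng.random(n_out) < 0.5, low, high)
        frame = tpl.drop(columns="_effect").copy()
        frame.insert(0, "subject_id", s + 1)
        frame["rt_raw"] = rt
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]


# ---------------------------------------------------------------------------
# trial CSV dialect
# ---------------------------------------------------------------------------

_STRING_COLUMNS = ("group", "kind", "structure", "ambiguity", "region")
_INT_COLUMNS = ("subject_id", "list_id", "stimulus_order", "word_index", "word_length")
_NULLABLE_INT_COLUMNS = ("block", "item_order")


def _normalize_trials(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _STRING_COLUMNS:
        df[col] = df[col].astype("object").where(df[col].notna(), None)
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("int64")
    for col in _NULLABLE_INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df["rt_raw"] = df["rt_raw"].astype(float)
    return df[list(TRIAL_COLUMNS)]


def write_trials(records: pd.DataFrame, path) -> None:
    """Write trial records in the canonical CSV dialect (empty = missing)."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise TrialParseError(f"records lack required columns: {missing}")
    _normalize_trials(records).to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV, validating schema; errors name the offending line."""
    try:
        df = pd.read_csv(path, dtype="object")
    except pd.errors.EmptyDataError:
        raise TrialParseError(f"{path}: file is empty (no header)") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing required columns {missing}")
    for col in _INT_COLUMNS + _NULLABLE_INT_COLUMNS + ("rt_raw",):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if col in _INT_COLUMNS:
            bad |= df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise TrialParseError(
                f"{path}: malformed value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = numeric
    if len(df) and (df["rt_raw"] <= 0).any():
        line = int((df["rt_raw"] <= 0).idxmax()) + 2
        raise TrialParseError(f"{path}: non-positive rt_raw at line {line}")
    return _normalize_trials(df)
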