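"""End-to-end orchestration of the synthetic study pipeline.

``prepare_dataset`` simulates the drawing cohort and the rater response
tables; ``run_experiment`` chains the per-experiment analyses (similarity
space, copy discrimination, category membership, part correspondence,
distinctiveness, part swapping) and writes CSV/JSON/SVG reports.  A
single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are reproducible
independently of each other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import correspondence as corr
from . import distinctiveness as dist
from . import similarity as sim
from . import stats as st
from . import swap as sw
from . import synthetic as syn
from .contour import STANDARD_N, self_intersects
from .io import save_dataset, write_svg

log = logging.getLogger("oneshotshapes")

__all__ = ["RunConfig", "prepare_dataset", "run_experiment",
           "validate_dataset", "EXPERIMENTS"]

EXPERIMENTS = ("exp2", "exp2b", "exp3", "exp4", "exp5", "exp6")

# stage indices for seed fan-out
_STAGES = {"cohort": 0, "similarity": 1, "exp2b": 2, "exp3": 3,
           "exp4": 4, "exp5": 5, "exp6": 6}


@dataclass
class RunConfig:
    seed: int = 0
    resample_n: int = STANDARD_N
    bins: int = 20                      # similarity-space bins (20 or 40)
    distinctiveness_threshold: float = 75.0
    null_reps: int = 10
    n_drawers: int = 17
    n_variations: int = 12
    n_exemplars: int = 8
    similarity_raters: int = 12
    classification_raters: int = 15
    correspondence_raters: int = 15
    correspondence_bundling: float = 0.35
    painting_raters: int = 10
    exp3_bins: int = 40
    exp4_shapes_per_category: int = 10
    exp5_shapes_per_category: int = 8
    swap_bases_per_cell: int = 5
    out_dir: Optional[str] = None

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGES[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def prepare_dataset(config: RunConfig) -> dict:
    """Simulate the cohort plus similarity ratings and aggregate scores."""
    log.info("stage=cohort seed=%d", config.stage_seed("cohort"))
    cohort = syn.generate_cohort(config.n_drawers, config.n_variations,
                                 config.n_exemplars,
                                 config.stage_seed("cohort"),
                                 resample_n=config.resample_n)
    placements = syn.simulate_similarity_ratings(
        cohort, config.similarity_raters,
        seed=config.stage_seed("similarity"))
    normalized = sim.normalize_table(placements)
    scores = sim.aggregate_similarity(normalized)
    log.info("stage=similarity placements=%d shapes=%d",
             len(placements), len(scores))
    return dict(config=config, cohort=cohort, placements=placements,
                normalized=normalized, scores=scores)


def _subset(data: dict, category: int, n: int) -> list:
    cat_scores = data["scores"][data["scores"]["category"] == category]
    return sim.select_spanning_subset(cat_scores, n)


def run_experiment(name: str, config: RunConfig,
                   data: Optional[dict] = None) -> dict:
    """Run one experiment's analysis chain; returns the report bundle.

    When ``config.out_dir`` is set the tables are also written as CSV
    (plus an SVG overlay for exp4/exp5 and a manifest).
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; one of {EXPERIMENTS}")
    if data is None:
        data = prepare_dataset(config)
    out = globals()[f"_run_{name}"](config, data)
    if config.out_dir:
        _write_report(name, config, data, out)
    return out


def _run_exp2(config: RunConfig, data: dict) -> dict:
    records = data["cohort"].records_frame()
    creativity = sim.creativity_index(records, data["scores"])
    per_drawer, pooled = sim.order_trend(records, data["scores"])
    subset = {cat: _subset(data, cat, config.bins)
              for cat in sorted(data["cohort"].exemplars)}
    return dict(scores=data["scores"], creativity=creativity,
                order_trend_per_drawer=per_drawer, order_trend=pooled,
                spanning_subset=subset)


def _run_exp2b(config: RunConfig, data: dict) -> dict:
    trials = syn.simulate_copy_discrimination(
        data["cohort"], n_raters=config.classification_raters,
        seed=config.stage_seed("exp2b"))
    k, n = int(trials["correct"].sum()), len(trials)
    test = st.binomial_test_one_sided(k, n, 0.5)
    return dict(trials=trials, k=k, n=n, proportion=k / n, test=test)


def _run_exp3(config: RunConfig, data: dict) -> dict:
    cohort = data["cohort"]
    shape_ids = [sid for cat in sorted(cohort.exemplars)
                 for sid in _subset(data, cat, config.exp3_bins)]
    choices = syn.simulate_classification(
        cohort, shape_ids, config.classification_raters,
        seed=config.stage_seed("exp3"))
    k = int((choices["response"] == choices["true_category"]).sum())
    n = len(choices)
    confusion = st.confusion_analysis(choices,
                                      n_categories=config.n_exemplars)
    overall = st.binomial_test_one_sided(k, n, 1 / config.n_exemplars)
    return dict(choices=choices, k=k, n=n, proportion=k / n,
                confusion=confusion, overall_test=overall)


def enumerate_exp4_trials(data: dict, config: RunConfig,
                          rng: np.random.Generator) -> list:
    """Per participant: 10 same-category + 10 cross-category pairs per
    exemplar (8 x 20 = 160 trials under defaults)."""
    cohort = data["cohort"]
    cats = sorted(cohort.exemplars)
    trials = []
    for cat in cats:
        same = _subset(data, cat, config.exp4_shapes_per_category)
        for sid in same:
            trials.append((f"t_{cat}_{sid}", sid, True))
        others = [c for c in cats if c != cat]
        for k in range(config.exp4_shapes_per_category):
            oc = others[int(rng.integers(len(others)))]
            pool = _subset(data, oc, config.exp4_shapes_per_category)
            sid = pool[int(rng.integers(len(pool)))]
            trials.append((f"t_{cat}_x{k}_{sid}", sid, False))
    return trials


def _run_exp4(config: RunConfig, data: dict) -> dict:
    cohort = data["cohort"]
    rng = np.random.default_rng(config.stage_seed("exp4"))
    trials = enumerate_exp4_trials(data, config, rng)
    pairs = syn.simulate_correspondence(
        cohort, trials, n_raters=config.correspondence_raters,
        bundling=config.correspondence_bundling,
        seed=config.stage_seed("exp4"))
    by_trial: dict = {}
    for p in pairs:
        by_trial.setdefault(p.trial, []).append(p)
    # within/cross area fractions and order/gap classification
    rows = []
    order_rows = []
    for trial_id, sid, same in trials:
        tpairs = by_trial.get(trial_id, [])
        cat = int(trial_id.split("_")[1])
        ex_contour, _ = cohort.exemplars[cat]
        runs = [(trial_id, f"r{r:02d}")
                for r in range(config.correspondence_raters)]
        frac = corr.corresponding_area_fraction(ex_contour, tpairs,
                                                all_trials=runs)
        rec = cohort.record(sid)
        rows.append(dict(trial=trial_id, shape=sid, same=same,
                         fraction=frac,
                         similarity=float(data["scores"].loc[sid, "s"])))
        if same and tpairs:
            rater0 = [p for p in tpairs if p.rater == "r00"]
            rel, gaps = analyze_trial_order(cohort, cat, rec, rater0)
            order_rows.append(dict(trial=trial_id, shape=sid,
                                   order=rel, n_gap_changes=len(gaps),
                                   truth=rec.order_class))
    frame = pd.DataFrame(rows)
    order_frame = pd.DataFrame(order_rows)
    within = frame.loc[frame["same"], "fraction"]
    cross = frame.loc[~frame["same"], "fraction"]
    t, df, p = st.t_test(within, cross)
    # regression of fraction on similarity bin midpoint
    bins = np.minimum((frame.loc[frame["same"], "similarity"]
                       * config.exp4_shapes_per_category).astype(int),
                      config.exp4_shapes_per_category - 1)
    grp = frame.loc[frame["same"]].groupby(bins)["fraction"].mean()
    mids = (grp.index + 0.5) / config.exp4_shapes_per_category
    trend = (corr.regress_area_on_similarity(grp.values, mids.values)
             if len(grp) >= 3 else None)
    decidable = order_frame[order_frame["order"].isin(
        ("identical", "reversed", "shuffled"))] if len(order_frame) else order_frame
    return dict(pairs=pairs, fractions=frame, orders=order_frame,
                within_mean=float(within.mean()),
                cross_mean=float(cross.mean()),
                t=t, df=df, p=p, trend=trend,
                decidable_fraction=(len(decidable) / len(order_frame)
                                    if len(order_frame) else float("nan")))


def analyze_trial_order(cohort, category, rec, rater_pairs
                        ) -> tuple[str, list]:
    """Part circles + order relation + gap changes for one rater's picks."""
    ex_contour, _ = cohort.exemplars[category]
    e_picks, v_picks = [], []
    for p in rater_pairs:
        if p.exemplar_pick.rest or p.variation_pick.rest:
            continue
        e_picks.append((p.label, p.exemplar_pick.segment(ex_contour)))
        v_picks.append((p.label, p.variation_pick.segment(rec.contour)))
    ecirc = corr.build_part_circle(ex_contour, e_picks)
    vcirc = corr.build_part_circle(rec.contour, v_picks)
    rel = corr.compare_part_order(ecirc, vcirc)
    shared = set(ecirc.labels()) & set(vcirc.labels())
    gaps = corr.classify_gap_changes(ecirc, vcirc) if shared else []
    return rel, gaps


def _run_exp5(config: RunConfig, data: dict) -> dict:
    cohort = data["cohort"]
    seed = config.stage_seed("exp5")
    shape_ids = [f"ex{cat}" for cat in sorted(cohort.exemplars)]
    for cat in sorted(cohort.exemplars):
        shape_ids += _subset(data, cat, config.exp5_shapes_per_category)
    paintings = syn.simulate_paintings(cohort, shape_ids,
                                       config.painting_raters, seed=seed)
    fields = {sid: dist.aggregate_paintings(p)
              for sid, p in paintings.items()}
    thr = config.distinctiveness_threshold

    def contour_of(sid):
        return (cohort.exemplars[int(sid[2:])][0] if sid.startswith("ex")
                else cohort.contour(sid))

    human_frac = {sid: dist.high_region_perimeter_fraction(
        fields[sid], contour_of(sid), thr) for sid in shape_ids}
    # randomized null per category
    rng = np.random.default_rng(seed + 1)
    by_cat: dict = {}
    for sid, plist in paintings.items():
        cat = (int(sid[2:]) if sid.startswith("ex")
               else cohort.record(sid).category)
        by_cat.setdefault(cat, []).extend(plist)
    null_frac = {}
    null_models = {cat: dist.fit_null_model(pl, cat)
                   for cat, pl in by_cat.items()}
    for sid in shape_ids:
        cat = (int(sid[2:]) if sid.startswith("ex")
               else cohort.record(sid).category)
        null_p = dist.sample_null_paintings(null_models[cat],
                                            contour_of(sid),
                                            config.null_reps, rng,
                                            shape_id=sid)
        nf = dist.aggregate_paintings(null_p)
        null_frac[sid] = dist.high_region_perimeter_fraction(
            nf, contour_of(sid), thr)
    ks_stat, ks_p = dist.compare_agreement(list(human_frac.values()),
                                           list(null_frac.values()))
    # exemplar-part vs variation-part score correlation (ground-truth spans)
    from .contour import ContourSegment
    seg_pairs = []
    for sid in shape_ids:
        if sid.startswith("ex"):
            continue
        rec = cohort.record(sid)
        espans = cohort.exemplar_spans[rec.category]
        ex_contour = cohort.exemplars[rec.category][0]
        for lab in rec.retained:
            es, el = espans[lab]
            vs, vl = rec.spans[lab]
            seg_pairs.append((ContourSegment(ex_contour, es, el),
                              ContourSegment(rec.contour, vs, vl)))
    all_fields = dict(fields)
    for sid in shape_ids:
        if sid.startswith("ex"):
            all_fields[sid] = fields[sid]
    r = p_r = float("nan")
    usable = [(e, v) for e, v in seg_pairs
              if (e.contour.shape_id in all_fields
                  and v.contour.shape_id in all_fields)]
    if len(usable) >= 3:
        r, p_r = dist.correlate_part_distinctiveness(
            usable,
            {sid: f for sid, f in all_fields.items()},
            {sid: f for sid, f in all_fields.items()})
    return dict(paintings=paintings, fields=fields,
                human_fractions=human_frac, null_fractions=null_frac,
                ks_stat=ks_stat, ks_p=ks_p,
                human_mean=float(np.mean(list(human_frac.values()))),
                null_mean=float(np.mean(list(null_frac.values()))),
                part_score_r=r, part_score_p=p_r,
                null_models=null_models)


def _run_exp6(config: RunConfig, data: dict,
              exp5: Optional[dict] = None) -> dict:
    cohort = data["cohort"]
    if exp5 is None:
        exp5 = _run_exp5(config, data)
    fields = exp5["fields"]
    cats = sorted(cohort.exemplars)
    shapes = {cat: [cohort.contour(sid) for sid in fields
                    if not sid.startswith("ex")
                    and cohort.record(sid).category == cat]
              for cat in cats}
    exemplars = {cat: cohort.exemplars[cat][0] for cat in cats}
    exemplar_fields = {cat: fields[f"ex{cat}"] for cat in cats}
    rng = np.random.default_rng(config.stage_seed("exp6"))
    stimuli, shortfalls = sw.build_swap_design(
        shapes, fields, exemplars, exemplar_fields, rng,
        bases_per_cell=config.swap_bases_per_cell,
        threshold=config.distinctiveness_threshold)
    # classification of swapped and unswapped shapes
    unswapped = [(sid, cohort.record(sid).category)
                 for sid in fields if not sid.startswith("ex")]
    table = syn.simulate_swap_classification(
        list(stimuli) + unswapped, cohort,
        n_raters=config.classification_raters,
        seed=config.stage_seed("exp6"))
    acc = table.groupby("condition")["correct"].mean().to_dict()
    h_indist = st.cohens_h(acc.get("none", np.nan),
                           acc.get("indistinctive", np.nan)).value
    h_dist = st.cohens_h(acc.get("none", np.nan),
                         acc.get("distinctive", np.nan)).value
    return dict(stimuli=stimuli, shortfalls=shortfalls, choices=table,
                accuracy=acc, cohens_h_indistinctive=float(h_indist),
                cohens_h_distinctive=float(h_dist),
                n_stimuli=len(stimuli))


# ---------------------------------------------------------------------------
# reports and validation

def _write_report(name: str, config: RunConfig, data: dict, out: dict
                  ) -> None:
    base = Path(config.out_dir) / name
    base.mkdir(parents=True, exist_ok=True)
    manifest = dict(experiment=name, config=asdict(config),
                    numpy=np.__version__, pandas=pd.__version__)
    (base / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for key, val in out.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(base / f"{key}.csv")
    scalars = {k: v for k, v in out.items()
               if isinstance(v, (int, float, str, bool))}
    (base / "summary.json").write_text(json.dumps(scalars, indent=1))
    if name == "exp5" and "fields" in out:
        colors = {}
        cohort = data["cohort"]
        for sid, f in out["fields"].items():
            contour = (cohort.exemplars[int(sid[2:])][0]
                       if sid.startswith("ex") else cohort.contour(sid))
            sat = (f.scores / 100.0)
            colors[contour.shape_id] = [
                f"rgb({int(255)},{int(255 * (1 - s))},{int(255 * (1 - s))})"
                for s in sat]
            write_svg([contour], base / f"{sid}.svg", point_colors=colors)
            colors = {}


def validate_dataset(path) -> list[dict]:
    """Structural checks of a dataset directory; returns findings."""
    from .io import load_dataset

    findings: list[dict] = []
    try:
        ds = load_dataset(path)
    except Exception as exc:  # noqa: BLE001
        return [dict(level="error", check="load", detail=str(exc))]
    ids = set()
    for c in ds["contours"]:
        ids.add(c.shape_id)
        if self_intersects(c):
            findings.append(dict(level="error", check="simple",
                                 detail=f"contour {c.shape_id} "
                                        "has crossing edges"))
    for tab, col in (("placements", "shape"), ("choices", "shape"),
                     ("picks", "shape")):
        if tab in ds:
            missing = set(ds[tab][col]) - ids
            if missing:
                findings.append(dict(level="error", check="referential",
                                     detail=f"{tab}.csv references unknown "
                                            f"shapes {sorted(missing)[:5]}"))
    if "paintings" in ds:
        p = ds["paintings"]
        for (rater, shape), grp in p.groupby(["rater", "shape"]):
            if not (grp["tier"] == 1).any():
                findings.append(dict(
                    level="error", check="tier1",
                    detail=f"painting {rater}/{shape} has no tier-1 area "
                           "(at least one part must be painted red)"))
    return findings
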