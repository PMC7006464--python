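"""End-to-end orchestration of the comparative color analysis.

``run_full`` executes the whole study pipeline on a directory of standard
inputs (two color tables, a tree file, background palettes, optionally body
sizes) and writes one tidy delimited table per analysis stage plus a JSON
manifest echoing the configuration and every derived seed:

cluster -> vectorize -> phylogenetic signal over trees -> Mantel ->
D / D_dif -> strategy classification -> transition table -> shared warning
color -> PGLS over trees.

Any stage failure aborts with the stage name; tables already written are
retained for inspection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .clustering import (
    DEFAULT_DARKNESS_THRESHOLD,
    DEFAULT_K,
    assign_clusters,
    fit_color_clusters,
    reduce_low_reflectance,
)
from .datamodel import StageDataset, ValidationError
from .decoupling import ddif_test, diversity_D, mantel, pca_colorspace
from .distances import background_distance, internal_contrast, pairwise_matrix
from .pgls import pgls_over_posterior
from .phylo import normalize_species_id
from .signal import signal_over_posterior
from .strategy import classify, shared_warning_color, transition_table, CATEGORIES
from .utils import derive_seed, write_manifest

__all__ = ["RunConfig", "run_full"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full pipeline run; echoed verbatim into the manifest."""

    caterpillar_table: str
    adult_table: str
    tree_file: str
    backgrounds: str
    out_dir: str
    body_sizes: str | None = None
    metric: str = "A"
    k: int = DEFAULT_K
    darkness_threshold: float = DEFAULT_DARKNESS_THRESHOLD
    n_perm_mantel: int = 10_000
    n_perm_ddif: int = 1000
    background_mode: str = "mean_pooled"
    thresholds: tuple[float, float] | str = "equal_width_terciles"
    hpd_prob: float = 0.95
    max_trees: int | None = None
    seed: int = 1

    def validate_paths(self) -> None:
        for name in ("caterpillar_table", "adult_table", "tree_file", "backgrounds"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.body_sizes is not None and not Path(self.body_sizes).exists():
            raise FileNotFoundError(f"body_sizes: {self.body_sizes} does not exist")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full(config: RunConfig) -> dict[str, Path]:
    """Run every analysis stage; returns a map of stage name -> output path."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: derive_seed(config.seed, s)
        for s in ("cluster", "mantel", "ddif", "signal")
    }
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        cat_patterns = oio.read_color_table(config.caterpillar_table)
        adult_patterns = oio.read_color_table(config.adult_table)
        trees = oio.read_trees(config.tree_file)
        if config.max_trees is not None:
            trees = trees[: config.max_trees]
        greens, browns = oio.read_backgrounds(config.backgrounds)

        stage = "cluster"
        all_rgb = np.array(
            [p.rgb for pat in cat_patterns + adult_patterns for p in pat.patches],
            float,
        )
        model = fit_color_clusters(all_rgb, k=config.k, seed=seeds["cluster"])
        model = reduce_low_reflectance(model, config.darkness_threshold)
        model.to_json(out / "cluster_model.json")
        written["cluster"] = out / "cluster_model.json"
        cat_patterns = assign_clusters(cat_patterns, model)
        adult_patterns = assign_clusters(adult_patterns, model)
        cats = oio.patterns_to_dataset(cat_patterns, "caterpillar", label="caterpillar")
        adults = oio.patterns_to_dataset(adult_patterns, "adult", label="adult")

        stage = "signal"
        comp = signal_over_posterior([cats, adults], trees, reference="adult")
        rows = [
            {"tree_index": i, "k_adult": kr, "k_caterpillar": ko, "difference": d}
            for i, (kr, ko, d) in enumerate(comp.per_tree["caterpillar"])
        ]
        sig_df = pd.DataFrame(rows)
        sig_df.to_csv(out / "signal.csv", index=False)
        written["signal"] = out / "signal.csv"

        stage = "mantel"
        common = sorted(set(cats.patterns) & set(adults.patterns))
        cats_m, adults_m = cats.subset(common), adults.subset(common)
        dm_cat = pairwise_matrix(cats_m, metric="A")
        dm_adult = pairwise_matrix(adults_m, metric="A")
        mres = mantel(
            dm_cat, dm_adult, n_perm=config.n_perm_mantel, seed=seeds["mantel"]
        )
        pd.DataFrame(
            [{"r": mres.r, "p_value": mres.p_value, "n_perm": mres.n_perm,
              "tail": mres.tail, "n_species": mres.n_species}]
        ).to_csv(out / "mantel.csv", index=False)
        written["mantel"] = out / "mantel.csv"

        stage = "ddif"
        dres = ddif_test(
            cats_m, adults_m, metric=config.metric,
            n_perm=config.n_perm_ddif, seed=seeds["ddif"],
        )
        pd.DataFrame(
            [{"metric": dres.metric, "d_caterpillar": dres.d_caterpillar,
              "d_adult": dres.d_adult, "d_dif": dres.d_dif,
              "p_lower": dres.p_lower, "p_upper": dres.p_upper,
              "n_perm": dres.n_perm}]
        ).to_csv(out / "ddif.csv", index=False)
        written["ddif"] = out / "ddif.csv"

        stage = "pca"
        pca_colorspace([cats, adults]).to_csv(out / "pca_scores.csv", index=False)
        written["pca"] = out / "pca_scores.csv"

        stage = "classify"
        scores_cat = {
            s: background_distance(cats[s], greens, browns, config.background_mode)
            for s in cats.species
        }
        scores_adult = {
            s: background_distance(adults[s], greens, browns, config.background_mode)
            for s in adults.species
        }
        # Pool both stages' scores for the automatic thresholds: one
        # histogram, one set of cut points, as the strategy bands are defined.
        if isinstance(config.thresholds, str):
            pooled = np.array(list(scores_cat.values()) + list(scores_adult.values()))
            lo, hi = pooled.min(), pooled.max()
            thr = (lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0)
        else:
            thr = config.thresholds
        calls_cat = classify(scores_cat, "caterpillar", thresholds=thr)
        calls_adult = classify(scores_adult, "adult", thresholds=thr)
        calls_df = pd.DataFrame(
            [dataclasses.asdict(c) for c in calls_cat + calls_adult]
        )
        calls_df.attrs["thresholds"] = thr
        calls_df.to_csv(out / "strategy_calls.csv", index=False)
        written["classify"] = out / "strategy_calls.csv"

        stage = "transitions"
        tt = transition_table(calls_cat, calls_adult)
        rows = [
            {"larval": lc, "adult": ac,
             "count": tt.cell(lc, ac),
             "percent": 100.0 * tt.cell(lc, ac) / tt.n_species}
            for lc in CATEGORIES for ac in CATEGORIES
        ]
        pd.DataFrame(rows).to_csv(out / "transitions.csv", index=False)
        written["transitions"] = out / "transitions.csv"

        stage = "shared_warning"
        flags, pct, n_eligible = shared_warning_color(
            calls_cat, calls_adult, cats, adults, model, config.darkness_threshold
        )
        pd.DataFrame(
            [{"species": sp, "same_warning_color": v} for sp, v in sorted(flags.items())]
        ).to_csv(out / "shared_warning_species.csv", index=False)
        pd.DataFrame(
            [{"n_eligible": n_eligible, "percent_same": pct}]
        ).to_csv(out / "shared_warning.csv", index=False)
        written["shared_warning"] = out / "shared_warning.csv"

        stage = "pgls_contrast"
        contrast_cat = {s: internal_contrast(cats[s]) for s in common}
        contrast_adult = {s: internal_contrast(adults[s]) for s in common}
        summ = pgls_over_posterior(
            contrast_adult, contrast_cat, trees, prob=config.hpd_prob
        )
        _write_pgls(summ, out / "pgls_contrast.csv")
        written["pgls_contrast"] = out / "pgls_contrast.csv"

        if config.body_sizes is not None:
            stage = "pgls_size"
            sizes = pd.read_csv(config.body_sizes)
            size_map = dict(zip(sizes["species"].astype(str), sizes["log_size_larval"]))
            norm_contrast = {normalize_species_id(s): v for s, v in contrast_cat.items()}
            y, x = {}, {}
            mu = np.mean(list(contrast_cat.values()))
            sd = np.std(list(contrast_cat.values())) or 1.0
            for sp, size in size_map.items():
                key = normalize_species_id(sp)
                if key in norm_contrast:
                    y[sp] = float(size)
                    x[sp] = (norm_contrast[key] - mu) / sd
            summ2 = pgls_over_posterior(y, x, trees, prob=config.hpd_prob)
            _write_pgls(summ2, out / "pgls_size.csv")
            written["pgls_size"] = out / "pgls_size.csv"
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageFailure(stage, exc) from exc

    write_manifest(out, dataclasses.asdict(config), seeds)
    written["manifest"] = out / "manifest.json"
    return written


def _write_pgls(summary, path: Path) -> None:
    rows = []
    for ti, fit in enumerate(summary.fits):
        for j, name in enumerate(fit.term_names):
            rows.append(
                {"tree_index": ti, "term": name, "estimate": fit.beta[j],
                 "se": fit.se[j], "t": fit.t[j], "p": fit.p[j]}
            )
    for j, name in enumerate(summary.term_names):
        rows.append(
            {"tree_index": "hpd_low", "term": name,
             "estimate": summary.hpd_estimate[j][0], "se": np.nan,
             "t": summary.hpd_t[j][0], "p": summary.hpd_p[j][0]}
        )
        rows.append(
            {"tree_index": "hpd_high", "term": name,
             "estimate": summary.hpd_estimate[j][1], "se": np.nan,
             "t": summary.hpd_t[j][1], "p": summary.hpd_p[j][1]}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
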