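"""Formats, validation, configuration, and the end-to-end pipeline driver.

CSV dialect: comma-separated, UTF-8, header row required, decimal point
(decimal commas are auto-detected and converted, with a log notice).
Internally all frequencies are Hz, durations seconds, and vocal tract
lengths meters. Selection tables use a Raven-style tab-separated layout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import combinations as comb
from . import phylo, repertoire
from .synth import CALL_TYPES

log = logging.getLogger("pacavoc")

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_element_csv",
    "write_element_csv",
    "read_combination_csv",
    "read_trait_csv",
    "read_newick",
    "read_selections",
    "write_selections",
    "RunConfig",
    "run_full_analysis",
]

ALPHA = 0.05  # global significance level

#: CSV column name -> canonical field; override per file layout.
DEFAULT_COLUMN_MAP = {
    "call_type": "call_type",
    "individual_id": "individual_id",
    "age_class": "age_class",
    "sex": "sex",
    "duration": "duration",
    "dominant_freq": "dominant_freq",
    "min_freq": "min_freq",
    "max_freq": "max_freq",
    "n_harmonics_under_1kHz": "n_harmonics_under_1kHz",
}

NUMERIC_FIELDS = ("duration", "dominant_freq", "min_freq", "max_freq")


class ValidationError(ValueError):
    pass


def _to_numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any() and series.dtype == object:
        # decimal-comma fallback
        retry = pd.to_numeric(
            series.astype(str).str.replace(",", ".", regex=False), errors="coerce"
        )
        if retry.notna().sum() > out.notna().sum():
            log.info("column %s: converted decimal commas to points", name)
            out = retry
    if out.isna().any():
        rows = out.index[out.isna()].tolist()[:5]
        raise ValidationError(f"non-numeric values in column {name!r} at rows {rows}")
    return out


def read_element_csv(
    path, column_map: Mapping[str, str] | None = None, allowed_types: Sequence[str] = CALL_TYPES
) -> pd.DataFrame:
    """Read and validate an element-parameter table.

    ``column_map`` maps file column names to canonical fields (the
    supplementary table's exact layout varies, so the mapping is
    configurable). Validates numeric fields, non-negative durations,
    min <= max frequencies, and known call-type labels.
    """
    raw = pd.read_csv(path)
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    missing = [src for src in cmap if src not in raw.columns]
    # drop optional columns that are simply absent
    for src in list(missing):
        if cmap[src] in ("sex", "age_class", "individual_id", "n_harmonics_under_1kHz"):
            cmap.pop(src)
            missing.remove(src)
    if missing:
        raise ValidationError(f"missing column(s) {missing} in {path}")
    df = raw[list(cmap)].rename(columns=cmap)
    for f in NUMERIC_FIELDS:
        df[f] = _to_numeric(df[f], f)
    bad_dur = df.index[df["duration"] <= 0].tolist()
    if bad_dur:
        raise ValidationError(f"non-positive duration at row(s) {bad_dur[:5]}")
    bad_rng = df.index[df["min_freq"] > df["max_freq"]].tolist()
    if bad_rng:
        raise ValidationError(f"min_freq > max_freq at row(s) {bad_rng[:5]}")
    if allowed_types is not None:
        unknown = sorted(set(df["call_type"]) - set(allowed_types))
        if unknown:
            raise ValidationError(f"unknown call-type label(s): {unknown}")
    counts = df["call_type"].value_counts()
    log.info("read %d elements (%s)", len(df), ", ".join(f"{k}: {v}" for k, v in counts.items()))
    return df


def write_element_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_combination_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("pattern", "duration"):
        if col not in df.columns:
            raise ValidationError(f"combination table missing column {col!r}")
    if "n_elements" not in df.columns:
        df["n_elements"] = df["pattern"].str.len()
    df["duration"] = _to_numeric(df["duration"], "duration")
    if "rhythm" not in df.columns:
        df["rhythm"] = df["n_elements"] / df["duration"]
    return df


def read_trait_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"species", "group_size_mid", "repertoire_size"}
    if not need <= set(df.columns):
        raise ValidationError(f"trait table must have columns {sorted(need)}")
    known = df.dropna(subset=["group_size_mid"])
    if (known["group_size_mid"] < 1).any() or (df["repertoire_size"] < 1).any():
        raise ValidationError("group sizes and repertoire sizes must be >= 1")
    return df


def read_newick(path) -> phylo.Phylogeny:
    text = Path(path).read_text()
    return phylo.Phylogeny.from_newick(text)


RAVEN_COLUMNS = ["Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]


def read_selections(path) -> list:
    """Raven-style tab-separated selection table -> ElementSelection list."""
    from .acoustics import ElementSelection

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RAVEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"selection table missing column(s) {missing}")
    return [
        ElementSelection(
            t_start=row[RAVEN_COLUMNS[0]],
            t_end=row[RAVEN_COLUMNS[1]],
            f_low=row[RAVEN_COLUMNS[2]],
            f_high=row[RAVEN_COLUMNS[3]],
        )
        for _, row in df.iterrows()
    ]


def write_selections(path, selections: Sequence) -> None:
    rows = [
        {
            RAVEN_COLUMNS[0]: s.t_start,
            RAVEN_COLUMNS[1]: s.t_end,
            RAVEN_COLUMNS[2]: s.f_low,
            RAVEN_COLUMNS[3]: s.f_high if math.isfinite(s.f_high) else 24000.0,
        }
        for s in selections
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run. Paths set to None skip stages."""

    element_csv: str | None = None
    combination_csv: str | None = None
    wav_paths: tuple[str, ...] = ()
    tree_path: str | None = None
    trait_csv: str | None = None
    focal_species: str = phylo.FOCAL_SPECIES
    attachment: str = "dasyprocta_cherry"
    positivize: bool = True
    interval: str = "prediction"
    features: tuple[str, ...] = repertoire.FEATURES
    lda_sd_ddof: int = 1
    truncation: str = "gap"
    spectrogram: dict = field(
        default_factory=lambda: {"window": 1460, "overlap": 0.9, "fft_size": 4096}
    )
    formant_settings: dict = field(
        default_factory=lambda: {
            "time_step": 0.01,
            "max_formants": 6,
            "max_formant": 11_000.0,
            "window": 0.01,
            "preemphasis": 50.0,
        }
    )
    chance_level: float = 1 / 8
    seed: int = 0
    out_dir: str | None = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute every configured stage and return one machine-readable report.

    Stages with missing inputs are skipped with a notice in the report.
    Any stage failure aborts with the stage name and cause. Defaults echo
    the reference analysis settings (Hann 1460/90%/4096 spectrograms, four
    discriminant features, alpha = 0.05) and are recorded in the report
    header so no setting defaults silently.
    """
    report: dict = {
        "settings": {
            "spectrogram": cfg.spectrogram,
            "features": list(cfg.features),
            "formants": cfg.formant_settings,
            "alpha": ALPHA,
            "seed": cfg.seed,
            "attachment": cfg.attachment,
            "positivize": cfg.positivize,
        },
        "skipped": [],
    }

    def stage(name):
        def wrap(fn):
            try:
                report[name] = fn()
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return wrap

    if cfg.element_csv:
        @stage("repertoire")
        def _():
            table = read_element_csv(cfg.element_csv)
            model = repertoire.fit_lda(table, cfg.features)
            wilks = repertoire.manova_wilks(table, cfg.features)
            cm = repertoire.loo_crossvalidate(table, cfg.features)
            pval = repertoire.binomial_vs_chance(
                cm.n_correct, cm.n_total, cfg.chance_level
            )
            return {
                "model": model.to_report(),
                "manova": wilks,
                "confusion": cm.counts.to_dict(orient="index"),
                "overall_accuracy": cm.overall_accuracy,
                "per_class_accuracy": cm.per_class_accuracy.to_dict(),
                "binomial_p": pval,
            }
    else:
        report["skipped"].append("repertoire (no element table)")

    if cfg.combination_csv:
        @stage("combinations")
        def _():
            records = read_combination_csv(cfg.combination_csv)
            means = comb.summarize_combinations(records)
            dendro = comb.ward_cluster(means)
            groups = comb.auto_truncate(dendro, method=cfg.truncation)
            return {
                "pattern_means": means.to_dict(orient="records"),
                "dendrogram_newick": dendro.to_newick(),
                "clusters": groups,
                "n_clusters": len(set(groups.values())),
            }
    else:
        report["skipped"].append("combinations (no combination table)")

    if cfg.wav_paths:
        @stage("formants")
        def _():
            from . import formants as fm
            from .acoustics import read_wav

            rows = []
            for p in cfg.wav_paths:
                track = fm.estimate_formants(read_wav(p), **cfg.formant_settings)
                disp = fm.measured_dispersion(track)
                rows.append(
                    {"wav": str(p), "df": disp.df, "sd_intervals": disp.sd_intervals,
                     "sd_fraction": disp.sd_fraction, "n_frames": disp.n_frames}
                )
            return {"calls": rows}
    else:
        report["skipped"].append("formants (no audio)")

    # the comparative stage always runs: the species data ship with the package
    @stage("contrasts")
    def _():
        traits = read_trait_csv(cfg.trait_csv) if cfg.trait_csv else phylo.load_caviomorph_traits()
        if cfg.tree_path:
            tree7 = read_newick(cfg.tree_path)
            if cfg.focal_species in tree7.tip_labels:
                raise ValidationError(
                    "tree_path must hold the background tree without the focal species"
                )
        else:
            tree7 = phylo.load_caviomorph_tree(include_focal=False)
        known = traits.dropna(subset=["group_size_mid"])
        rep = {r.species: math.log10(r.repertoire_size) for r in traits.itertuples()}
        gs = {r.species: math.log10(r.group_size_mid) for r in known.itertuples()}
        tree = phylo.nee_branch_lengths(tree7)
        cx, cy = phylo.pic(tree, rep), phylo.pic(tree, gs)
        reg = phylo.fit_contrast_regression(cx, cy, positivize=cfg.positivize)
        out = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "f_statistic": reg.f_statistic,
            "df": list(reg.df),
            "p": reg.p_value,
            "contrasts_x": cx.to_frame().to_dict(orient="records"),
            "contrasts_y": cy.to_frame().to_dict(orient="records"),
        }
        if cfg.focal_species in set(traits.species):
            full = phylo.nee_branch_lengths(
                phylo.attach_focal(tree7, cfg.focal_species, cfg.attachment)
            )
            pred = phylo.predict_group_size(
                reg, full, rep, gs, focal=cfg.focal_species, interval=cfg.interval
            )
            out["prediction"] = {
                "x_contrast": pred.x_contrast,
                "y_contrast": pred.y_contrast,
                "log10_group_size": pred.log10_group_size,
                "group_size": pred.group_size,
                "interval": list(pred.interval),
                "interval_kind": pred.interval_kind,
                "attachment": cfg.attachment,
            }
        return out

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default)
        )
    return report
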