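"""Readers and writers for the plain-text interchange formats.

Color tables are delimited text (comma by default, tab accepted) with header
columns ``species, stage, sex, side, r, g, b, area_category`` — one row per
color patch.  Trees are Newick or NEXUS via dendropy; NEXUS files may carry a
whole posterior sample.  Distance matrices export as square labeled tables or
long form.  Background palettes are JSON ``{"greens": [[r,g,b],...],
"browns": [...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datamodel import ColorPatch, ColorPattern, StageDataset, ValidationError

__all__ = [
    "read_color_table",
    "write_color_table",
    "patterns_to_dataset",
    "read_trees",
    "write_trees",
    "read_backgrounds",
    "write_backgrounds",
    "write_distance_matrix",
    "read_distance_matrix",
]

REQUIRED_COLUMNS = ("species", "stage", "sex", "side", "r", "g", "b", "area_category")


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_color_table(path: str | Path) -> list[ColorPattern]:
    """Read a patch-per-row color table, grouping rows into ColorPatterns.

    Rows sharing (species, stage, sex, side) form one pattern, in file order.
    Raises :class:`ValidationError` naming the offending row on any bound or
    schema violation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    patterns: list[ColorPattern] = []
    grouped: dict[tuple, list[tuple[int, ColorPatch]]] = {}
    order: list[tuple] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        try:
            patch = ColorPatch(
                r=int(row["r"]),
                g=int(row["g"]),
                b=int(row["b"]),
                area_category=int(row["area_category"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path} line {rownum}: {exc}") from exc
        key = (
            str(row["species"]).strip(),
            str(row["stage"]).strip(),
            str(row["sex"]).strip(),
            str(row["side"]).strip(),
        )
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((rownum, patch))

    for key in order:
        species, stage, sex, side = key
        rows = grouped[key]
        try:
            patterns.append(
                ColorPattern(
                    species_id=species,
                    stage=stage,
                    sex=sex,
                    side=side,
                    patches=tuple(p for _, p in rows),
                )
            )
        except ValidationError as exc:
            lines = ", ".join(str(n) for n, _ in rows)
            raise ValidationError(f"{path} lines {lines}: {exc}") from exc
    return patterns


def write_color_table(patterns: list[ColorPattern], path: str | Path, sep: str = ",") -> None:
    rows = []
    for p in patterns:
        for patch in p.patches:
            rows.append(
                {
                    "species": p.species_id,
                    "stage": p.stage,
                    "sex": p.sex,
                    "side": p.side,
                    "r": patch.r,
                    "g": patch.g,
                    "b": patch.b,
                    "area_category": patch.area_category,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


def patterns_to_dataset(
    patterns: list[ColorPattern],
    stage: str,
    sex: str | None = None,
    side: str | None = None,
    label: str | None = None,
) -> StageDataset:
    """Select the patterns matching a stage (and optionally sex/side)."""
    selected = [
        p
        for p in patterns
        if p.stage == stage
        and (sex is None or p.sex == sex)
        and (side is None or p.side == side)
    ]
    label = label or "-".join(
        x for x in (stage, sex, side) if x and x != "unspecified"
    )
    ds = StageDataset(label=label)
    for p in selected:
        ds.add(p)
    return ds


# ---------------------------------------------------------------------------
# Trees


def read_trees(path: str | Path, schema: str | None = None) -> list[dendropy.Tree]:
    """Read one or more rooted trees from Newick or NEXUS.

    Plain Newick without a rooting comment is treated as rooted (the standard
    comparative-methods convention for time-calibrated trees); an explicit
    ``[&U]`` flag raises an error since Brownian covariances need a root.
    """
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".trees"} else "newick"
    trees = dendropy.TreeList.get(
        path=str(path), schema=schema, rooting="default-rooted"
    )
    if not trees:
        raise ValidationError(f"{path}: no trees found")
    for i, t in enumerate(trees):
        if not t.is_rooted:
            raise ValidationError(f"{path}: tree {i} is explicitly unrooted")
    return list(trees)


def write_trees(trees: list[dendropy.Tree], path: str | Path, schema: str = "newick") -> None:
    tl = dendropy.TreeList(trees)
    tl.write(path=str(path), schema=schema, suppress_rooting=(schema == "newick"))


# ---------------------------------------------------------------------------
# Backgrounds


def read_backgrounds(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    greens = np.asarray(data["greens"], float)
    browns = np.asarray(data["browns"], float)
    for name, arr in (("greens", greens), ("browns", browns)):
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(f"{path}: {name} must be a list of RGB triples")
        if arr.min() < 0 or arr.max() > 255:
            raise ValidationError(f"{path}: {name} outside channel bounds")
    return greens, browns


def write_backgrounds(greens: np.ndarray, browns: np.ndarray, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "greens": np.asarray(greens, float).tolist(),
                "browns": np.asarray(browns, float).tolist(),
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(
    labels: list[str],
    values: np.ndarray,
    path: str | Path,
    form: str = "square",
    sep: str = ",",
) -> None:
    """Export a labeled symmetric matrix, square or long (sp1, sp2, distance)."""
    values = np.asarray(values, float)
    if form == "square":
        pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep=sep)
    elif form == "long":
        rows = [
            {"sp1": labels[i], "sp2": labels[j], "distance": values[i, j]}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown form {form!r}")


def read_distance_matrix(path: str | Path, sep: str = ",") -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return [str(c) for c in df.index], df.to_numpy(float)
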