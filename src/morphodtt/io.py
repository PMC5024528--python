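"""File formats: TPS landmark files, Newick trees, and the tab-separated
age / group / time-bin tables, plus cross-file consistency checks.

The TPS dialect accepted here is the tpsDig2 core: ``LM=<n>`` followed by
``n`` whitespace-separated coordinate lines, an optional ``SCALE=<s>`` that
multiplies the coordinates, and ``ID=`` or ``IMAGE=`` supplying the taxon
label.  CURVES/POINTS sub-records are not interpreted; semilandmark roles
are supplied separately because landmarks and semilandmarks are treated as
equivalent throughout the pipeline.  The y axis increases upward (tpsDig
convention); no image-origin flipping is performed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "TpsParseError",
    "ValidationError",
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_age_table",
    "read_bin_table",
    "read_group_table",
    "validate_dataset",
]


class TpsParseError(ValueError):
    """Malformed TPS record; the message names the offending record index."""


class ValidationError(ValueError):
    """Cross-file or table-level consistency failure."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark coordinates.

    Parameters
    ----------
    taxon : str
        Specimen / taxon label.
    coords : (k, 2) ndarray
        Landmark coordinates in digitizing units.
    roles : sequence of {"fixed", "semi"}, optional
        Per-point role flags.  Roles do not alter any computation (semis are
        treated as ordinary landmarks) but must be uniform across a dataset.
    """

    taxon: str
    coords: np.ndarray
    roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2); got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in configuration {self.taxon!r}")
        if self.roles is not None:
            self.roles = tuple(self.roles)
            if len(self.roles) != len(self.coords):
                raise ValueError("roles length must match landmark count")
            bad = set(self.roles) - {"fixed", "semi"}
            if bad:
                raise ValueError(f"unknown landmark roles: {sorted(bad)}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of :class:`LandmarkConfiguration`.

    Records appear in file order.  All records must share one landmark
    count.  ``SCALE=`` lines multiply the record's coordinates.
    """
    text = Path(path).read_text(encoding="utf-8")
    configs: list[LandmarkConfiguration] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    rec_index = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"record {rec_index}: expected LM= line, got {line!r}"
            )
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"record {rec_index}: bad LM= count {line!r}") from exc
        i += 1
        coords = np.empty((n_lm, 2), dtype=float)
        for j in range(n_lm):
            if i >= len(lines) or "=" in lines[i] or not lines[i]:
                raise TpsParseError(
                    f"record {rec_index}: expected {n_lm} coordinate lines, got {j}"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"record {rec_index}: coordinate line {j} is not an x y pair: "
                    f"{lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TpsParseError(
                    f"record {rec_index}: non-numeric coordinate on line {j}: "
                    f"{lines[i]!r}"
                ) from exc
            i += 1
        label: str | None = None
        scale: float | None = None
        while i < len(lines) and lines[i] and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "ID":
                label = value
            elif key == "IMAGE" and label is None:
                label = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"record {rec_index}: non-numeric SCALE= value {value!r}"
                    ) from exc
            # CURVES=/POINTS=/COMMENT= etc. are tolerated and ignored
            i += 1
        if label is None:
            raise TpsParseError(f"record {rec_index}: missing ID= or IMAGE= label")
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(taxon=label, coords=coords))
        rec_index += 1
    if not configs:
        raise TpsParseError("no TPS records found")
    counts = {c.n_landmarks for c in configs}
    if len(counts) > 1:
        raise TpsParseError(
            f"landmark counts differ across records: {sorted(counts)}"
        )
    return configs


def write_tps(path: str | Path, configs: list[LandmarkConfiguration]) -> None:
    """Write configurations as a TPS file (full float precision)."""
    buf = _io.StringIO()
    for cfg in configs:
        buf.write(f"LM={cfg.n_landmarks}\n")
        for x, y in cfg.coords:
            buf.write(f"{float(x)!r} {float(y)!r}\n")
        buf.write(f"ID={cfg.taxon}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; polytomies are preserved.

    Raises ``ValidationError`` on duplicate tip labels.
    """
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in tree: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True), encoding="utf-8"
    )


_AGE_COLUMNS = ("taxon", "fad", "lad", "group")


def read_age_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated taxon age table.

    Columns: ``taxon``, ``fad`` (first appearance, Ma), ``lad`` (last
    appearance, Ma), ``group``.  Validates ``fad >= lad > 0`` and unique
    taxon names.  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _AGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"age table missing columns: {missing}")
    df = df[list(_AGE_COLUMNS)].copy()
    df["fad"] = df["fad"].astype(float)
    df["lad"] = df["lad"].astype(float)
    dupes = df["taxon"][df["taxon"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate taxa in age table: {dupes}")
    bad = df[(df["fad"] < df["lad"]) | (df["lad"] <= 0)]
    if not bad.empty:
        raise ValidationError(
            "age table rows violate fad >= lad > 0: "
            + ", ".join(bad["taxon"].tolist())
        )
    return df


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Read the time-bin table (``name``, ``older``, ``younger`` in Ma).

    Bins must be internally consistent (older > younger), non-overlapping
    and ordered old to young.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("name", "older", "younger") if c not in df.columns]
    if missing:
        raise ValidationError(f"bin table missing columns: {missing}")
    df = df[["name", "older", "younger"]].copy()
    df["older"] = df["older"].astype(float)
    df["younger"] = df["younger"].astype(float)
    bad = df[df["older"] <= df["younger"]]
    if not bad.empty:
        raise ValidationError(
            "bins with older <= younger: " + ", ".join(bad["name"].tolist())
        )
    for prev, cur in zip(df.itertuples(), df.iloc[1:].itertuples()):
        if cur.older > prev.younger:
            raise ValidationError(
                f"bins {prev.name!r} and {cur.name!r} overlap or are out of "
                "old-to-young order"
            )
    return df


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated taxon-to-group map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"taxon", "group"} <= set(df.columns):
        raise ValidationError("group table needs columns: taxon, group")
    dupes = df["taxon"][df["taxon"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate taxa in group table: {dupes}")
    return dict(zip(df["taxon"], df["group"]))


def validate_dataset(
    configs: list[LandmarkConfiguration],
    tree: dendropy.Tree,
    ages: pd.DataFrame,
) -> None:
    """Check tree tips ⊆ age-table taxa ⊆ landmark taxa.

    Raises ``ValidationError`` naming every mismatched taxon; a pass means
    the three sources join completely on the tree's tip set.
    """
    tps_taxa = {c.taxon for c in configs}
    age_taxa = set(ages["taxon"])
    tip_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    problems = []
    missing_ages = sorted(tip_taxa - age_taxa)
    if missing_ages:
        problems.append(f"tree tips missing from age table: {missing_ages}")
    missing_shapes = sorted(age_taxa - tps_taxa)
    if missing_shapes:
        problems.append(f"age-table taxa missing from landmark data: {missing_shapes}")
    if problems:
        raise ValidationError("; ".join(problems))
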