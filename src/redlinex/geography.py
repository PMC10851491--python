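"""Apportionment of HOLC security-map grades to Census block groups.

The Home Owners Loan Corporation (HOLC) graded urban neighborhoods A
("Best") through D ("Hazardous"); a handful of areas carry an undocumented
grade E, which is passed through unchanged.  HOLC polygons do not align
with modern Census geography, so each block group is assigned a grade by a
population-threshold rule operating at the Census *block* level — the
finest unit with national population counts:

1. every block's population is binned into the grade of the HOLC polygon
   containing the block centroid (point-in-polygon), or into an
   ``Unclassified`` bin when no polygon contains it;
2. a block group receives the label of the single bin holding strictly
   more than a threshold fraction (default 0.9) of its total population;
   if no bin qualifies the block group is ``Ambiguous``.

Unlike areal-overlap apportionment this makes no uniform-density
assumption.  ``redlined`` means label D.  All geometry is planar; the
module never reprojects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

GRADES: tuple[str, ...] = ("A", "B", "C", "D", "E")
UNCLASSIFIED = "Unclassified"
AMBIGUOUS = "Ambiguous"
#: bin labels in the order stored in a crosswalk row
BIN_LABELS: tuple[str, ...] = GRADES + (UNCLASSIFIED,)

_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}


class GeoidFormatError(ValueError):
    """Raised for identifiers that are not 15-digit Census block GEOIDs."""


class ZeroPopulationError(ValueError):
    """Raised when an operation requires population but the total is zero."""


def truncate_block_geoid(geoid15: str) -> str:
    """Return the 12-character block-group GEOID prefix of a block GEOID.

    Census block identifiers are 15 digits; the first 12 identify the
    parent block group.
    """
    if (
        not isinstance(geoid15, str)
        or len(geoid15) != 15
        or not geoid15.isdigit()
    ):
        raise GeoidFormatError(
            f"expected a 15-digit Census block GEOID, got {geoid15!r}"
        )
    return geoid15[:12]


@dataclass(frozen=True)
class HOLCPolygon:
    """One graded HOLC security-map area in planar coordinates."""

    grade: str
    geometry: shapely.Geometry

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"HOLC grade must be one of {GRADES}, got {self.grade!r}")
        if not self.geometry.is_valid:
            object.__setattr__(self, "geometry", shapely.make_valid(self.geometry))


@dataclass(frozen=True)
class GradeAssignment:
    """Label of one block group under a population threshold."""

    geoid12: str
    label: str
    threshold: float
    redlined: bool
    shares: Mapping[str, float]


def read_holc_geojson(path) -> list[HOLCPolygon]:
    """Read HOLC polygons from a GeoJSON FeatureCollection with a ``grade`` property."""
    with open(path) as fh:
        fc = json.load(fh)
    return [
        HOLCPolygon(grade=f["properties"]["grade"], geometry=geom_shape(f["geometry"]))
        for f in fc["features"]
    ]


def write_holc_geojson(polygons: Iterable[HOLCPolygon], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"grade": p.grade},
                "geometry": geom_mapping(p.geometry),
            }
            for p in polygons
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def _validate_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    required = {"geoid15", "x", "y", "population"}
    missing = required - set(blocks.columns)
    if missing:
        raise ValueError(f"blocks frame missing columns: {sorted(missing)}")
    ids = blocks["geoid15"].astype(str)
    bad = ~(ids.str.len().eq(15) & ids.str.isdigit())
    if bad.any():
        raise GeoidFormatError(
            f"{int(bad.sum())} block GEOIDs are not 15-digit strings "
            f"(first offender: {ids[bad].iloc[0]!r})"
        )
    if (blocks["population"] < 0).any():
        raise ValueError("block populations must be non-negative")
    out = blocks.copy()
    out["geoid15"] = ids
    return out


def bin_population(
    blocks: pd.DataFrame, holc: Sequence[HOLCPolygon]
) -> pd.DataFrame:
    """Bin block populations into HOLC grades per block group.

    Parameters
    ----------
    blocks
        Frame with columns ``geoid15``, ``x``, ``y``, ``population``; the
        (x, y) centroid must be in the same planar system as the polygons.
    holc
        HOLC polygons.  A centroid on a polygon boundary counts as
        contained.  If several polygons contain one centroid the worst
        grade (latest in A<B<C<D<E) wins and the event is logged.

    Returns
    -------
    DataFrame indexed by ``geoid12`` with one column per bin label
    (A..E, Unclassified) plus ``total_population``.  Population is
    conserved: bins sum to the block-group total.
    """
    blocks = _validate_blocks(blocks)
    n = len(blocks)
    bin_of_block = np.full(n, len(GRADES), dtype=int)  # sentinel = Unclassified

    if holc and n:
        pts = shapely.points(
            blocks["x"].to_numpy(float), blocks["y"].to_numpy(float)
        )
        tree = STRtree([p.geometry for p in holc])
        # point.intersects(polygon) is true on the boundary: closed containment
        pt_idx, poly_idx = tree.query(pts, predicate="intersects")
        ranks = np.array([_GRADE_RANK[holc[i].grade] for i in poly_idx], dtype=int)
        best = np.full(n, -1, dtype=int)
        np.maximum.at(best, pt_idx, ranks)
        hits = np.bincount(pt_idx, minlength=n)
        n_overlap = int((hits > 1).sum())
        if n_overlap:
            log.warning(
                "%d block centroids fall in overlapping HOLC polygons; "
                "assigned the worse grade",
                n_overlap,
            )
        contained = best >= 0
        bin_of_block[contained] = best[contained]

    labels = np.array(BIN_LABELS)[bin_of_block]
    df = pd.DataFrame(
        {
            "geoid12": blocks["geoid15"].str[:12].to_numpy(),
            "label": labels,
            "population": blocks["population"].to_numpy(),
        }
    )
    bins = (
        df.pivot_table(
            index="geoid12",
            columns="label",
            values="population",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=list(BIN_LABELS), fill_value=0)
        .rename_axis(columns=None)
    )
    bins["total_population"] = bins[list(BIN_LABELS)].sum(axis=1)
    return bins


def assign_grade(
    bins: Mapping[str, float] | pd.Series, threshold: float, geoid12: str = ""
) -> GradeAssignment:
    """Label one block group from its grade bins at a population threshold.

    The label is the bin holding *strictly* more than ``threshold`` of the
    total population; at exactly the threshold, or when no bin qualifies,
    the block group is ``Ambiguous``.  With ``threshold > 0.5`` at most
    one bin can qualify; below 0.5 the largest qualifying bin wins, with
    ties labelled Ambiguous.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    total = float(sum(bins[k] for k in BIN_LABELS))
    if total <= 0:
        raise ZeroPopulationError(
            f"block group {geoid12 or '<unknown>'} has zero total population"
        )
    shares = {k: float(bins[k]) / total for k in BIN_LABELS}
    qualifying = [k for k in BIN_LABELS if shares[k] > threshold]
    if len(qualifying) == 1:
        label = qualifying[0]
    elif len(qualifying) > 1:
        top = max(shares[k] for k in qualifying)
        winners = [k for k in qualifying if shares[k] == top]
        label = winners[0] if len(winners) == 1 else AMBIGUOUS
    else:
        label = AMBIGUOUS
    return GradeAssignment(
        geoid12=geoid12,
        label=label,
        threshold=threshold,
        redlined=(label == "D"),
        shares=shares,
    )


def assign_grades(bins: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Vectorised :func:`assign_grade` over a :func:`bin_population` frame.

    Block groups with zero total population are excluded (the analysis
    drops their records upstream) and counted in the log.

    Returns a crosswalk frame indexed by geoid12 with columns ``label``,
    ``redlined``, ``threshold`` and one ``share_<bin>`` per bin.
    """
    nonzero = bins["total_population"] > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        log.info("excluding %d zero-population block groups from crosswalk", n_zero)
    rows = []
    for geoid12, row in bins.loc[nonzero].iterrows():
        a = assign_grade(row, threshold, geoid12=str(geoid12))
        rec = {
            "geoid12": a.geoid12,
            "label": a.label,
            "redlined": a.redlined,
            "threshold": a.threshold,
        }
        rec.update({f"share_{k}": a.shares[k] for k in BIN_LABELS})
        rows.append(rec)
    out = pd.DataFrame(
        rows,
        columns=["geoid12", "label", "redlined", "threshold"]
        + [f"share_{k}" for k in BIN_LABELS],
    )
    return out.set_index("geoid12")
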