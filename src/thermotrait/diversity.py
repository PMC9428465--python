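"""Community structure metrics from colony-count tables.

Given end-of-experiment colony counts per (temperature, replicate, taxon),
this module computes relative abundances p_i = n_i / N, species richness R
(taxa with positive count), Shannon diversity H' = -sum p_i ln p_i (nats),
Pielou's evenness J = H'/ln R (undefined for monocultures, where ln R = 0),
and rank-abundance curves.  A prevalence filter removes, within each
temperature, taxa present in no more than a given fraction of that
temperature's replicate communities, so that rare taxa do not drive the
downstream statistics.

Natural logarithms are used throughout, which makes J = 1 exactly for a
perfectly even community of any richness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIVERSITY_COLUMNS = ["temp_c", "replicate", "richness", "shannon_h", "pielou_j"]


class EmptyCommunityError(ValueError):
    """Raised when an operation needs at least one individual and gets none."""


def _as_count_series(counts) -> pd.Series:
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    return s


def relative_abundance(counts) -> pd.Series:
    """Proportions p_i = count_i / total, indexed by taxon.

    Raises :class:`EmptyCommunityError` for an all-zero community.
    """
    s = _as_count_series(counts)
    total = s.sum()
    if total <= 0:
        raise EmptyCommunityError("community has no individuals")
    return s / total


def shannon(proportions) -> float:
    """Shannon diversity H' = -sum p_i ln p_i in nats, with 0 ln 0 = 0."""
    p = np.asarray(pd.Series(proportions, dtype=float))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum():.12g}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def richness(counts) -> int:
    """Number of taxa with a positive count."""
    return int((_as_count_series(counts) > 0).sum())


def pielou(shannon_h: float, richness_r: int) -> float:
    """Pielou's evenness J = H'/ln R; NaN for R = 1 (genuinely undefined).

    Raises :class:`EmptyCommunityError` for R = 0.
    """
    if richness_r == 0:
        raise EmptyCommunityError("evenness of an empty community")
    if richness_r < 0:
        raise ValueError("richness must be non-negative")
    if shannon_h < 0:
        raise ValueError("Shannon H' must be non-negative")
    if richness_r == 1:
        return float("nan")
    return float(shannon_h / np.log(richness_r))


def rank_abundance(counts) -> pd.DataFrame:
    """Proportions sorted descending with ranks 1..R (zero counts dropped).

    Ties are broken by taxon label ascending.  Returns a DataFrame with
    columns ``rank, taxon, proportion``.
    """
    props = relative_abundance(counts)
    props = props[props > 0]
    ordered = props.sort_index(ascending=True).sort_values(
        ascending=False, kind="stable")
    return pd.DataFrame({
        "rank": np.arange(1, ordered.size + 1),
        "taxon": ordered.index.to_numpy(),
        "proportion": ordered.to_numpy(),
    })


def filter_rare(table: pd.DataFrame, min_prevalence: float = 0.25) -> pd.DataFrame:
    """Drop taxa present in no more than ``min_prevalence`` of replicates,
    independently within each temperature.

    Presence means count > 0; a taxon is kept at a temperature only if its
    prevalence there is *strictly* greater than ``min_prevalence`` ("more
    than 25%" by default).  Removals are per-temperature: a taxon common at
    20 degC but rare at 35 degC keeps its 20 degC records only.  The
    operation is idempotent.
    """
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValueError("min_prevalence must lie in [0, 1]")
    keep_masks = []
    for temp, sub in table.groupby("temp_c", sort=False):
        n_reps = sub["replicate"].nunique()
        present = sub[sub["count"] > 0].groupby("taxon")["replicate"].nunique()
        prevalence = present / n_reps
        keep = set(prevalence[prevalence > min_prevalence].index)
        dropped = sorted(set(sub["taxon"]) - keep)
        if dropped:
            logger.info("prevalence filter @%s degC: removed %s", temp, dropped)
        keep_masks.append((table["temp_c"] == temp) & table["taxon"].isin(keep))
    if not keep_masks:
        return table.copy()
    mask = np.logical_or.reduce([m.to_numpy() for m in keep_masks])
    return table[mask].reset_index(drop=True)


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate richness, Shannon H' and Pielou J from a count table.

    Replicates with no individuals are emitted with richness 0 and missing
    H'/J (logged).  Returns a DataFrame with ``temp_c, replicate, richness,
    shannon_h, pielou_j``.
    """
    rows = []
    for (temp, rep), sub in table.groupby(["temp_c", "replicate"], sort=True):
        counts = sub.set_index("taxon")["count"]
        r = richness(counts)
        if r == 0:
            logger.warning("empty community at %s degC replicate %s", temp, rep)
            rows.append((temp, rep, 0, np.nan, np.nan))
            continue
        h = shannon(relative_abundance(counts))
        rows.append((temp, rep, r, h, pielou(h, r)))
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS)


def abundance_long(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format relative abundances per (temp_c, replicate, taxon).

    Empty replicates are skipped with a warning.
    """
    rows = []
    for (temp, rep), sub in table.groupby(["temp_c", "replicate"], sort=True):
        counts = sub.set_index("taxon")["count"]
        if counts.sum() <= 0:
            logger.warning("skipping empty community at %s degC replicate %s",
                           temp, rep)
            continue
        props = relative_abundance(counts)
        for taxon, p in props.items():
            rows.append((temp, rep, taxon, float(p)))
    return pd.DataFrame(rows, columns=["temp_c", "replicate", "taxon", "rel_abund"])


def abundance_matrix(table: pd.DataFrame):
    """Pivot a count table to a (replicate x taxon) relative-abundance matrix.

    Returns ``(matrix, meta)`` where ``matrix`` is a DataFrame with one row
    per (temp_c, replicate) and one column per taxon (missing taxa filled
    with 0), rows normalised to sum to 1, and ``meta`` is the aligned
    DataFrame of ``temp_c, replicate``.
    """
    wide = table.pivot_table(index=["temp_c", "replicate"], columns="taxon",
                             values="count", fill_value=0, aggfunc="sum")
    totals = wide.sum(axis=1)
    nonempty = totals > 0
    if (~nonempty).any():
        logger.warning("dropping %d empty communities from abundance matrix",
                       int((~nonempty).sum()))
    wide = wide[nonempty]
    mat = wide.div(wide.sum(axis=1), axis=0)
    meta = mat.index.to_frame(index=False)
    return mat.reset_index(drop=True), meta
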