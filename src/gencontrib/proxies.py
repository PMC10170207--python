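"""Fitness proxies, analysis eligibility, and lineage-fate accounting.

Four per-individual fitness proxies are computed from the pedigree:

* lifespan — death year minus birth year;
* LRS — lifetime number of offspring born;
* LRS_SA — number of offspring surviving to adulthood, where adulthood is
  the sex-specific 5th percentile of age at first reproduction over the
  whole dataset;
* grandoffspring — total offspring of an individual's offspring, defined
  only when every offspring has a complete life history (known birth and
  death years).

Eligibility flags mirror the analysis filters: ``eligible_core`` (IGC
estimated, own birth and death known), ``eligible_grand`` (additionally all
offspring complete), ``eligible_model`` (informative for every model
predictor).  Lineage-fate accounting classifies each focal's deceased
descendants as having continued the lineage locally, still alive without
reproducing, or failed (died or emigrated without reproducing locally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .igc import IGCSeries
from .migration import EMIGRANT, MigrationStatus
from .pedigree import FEMALE, MALE, PedigreeTable, descendants

logger = logging.getLogger("gencontrib")


@dataclass(frozen=True)
class AdulthoodThreshold:
    """Sex-specific adulthood ages (years); ``pooled`` is used for offspring
    of unknown sex."""

    female: float
    male: float
    pooled: float


def _ages_at_first_reproduction(ped: PedigreeTable) -> pd.DataFrame:
    rows = []
    for rec in ped:
        if rec.birth_year is None:
            continue
        child_years = [
            ped[c].birth_year
            for c in ped.child_index.get(rec.id, ())
            if ped[c].birth_year is not None
        ]
        if child_years:
            rows.append({"sex": rec.sex, "age": min(child_years) - rec.birth_year})
    return pd.DataFrame(rows, columns=["sex", "age"])


def adulthood_threshold(
    ped: PedigreeTable,
    percentile: float = 5.0,
    method: str = "linear",
    min_reproducers: int = 20,
) -> AdulthoodThreshold:
    """Sex-specific ``percentile`` (default 5th) of age at first reproduction.

    ``method`` is passed to :func:`numpy.percentile` (default the
    linear-interpolation "type 7" definition).  Requires at least
    ``min_reproducers`` reproducing individuals of each sex with known birth
    years.
    """
    ages = _ages_at_first_reproduction(ped)
    out = {}
    for sex, label in ((FEMALE, "female"), (MALE, "male")):
        vals = ages.loc[ages["sex"] == sex, "age"].to_numpy(dtype=float)
        if len(vals) < min_reproducers:
            raise ValueError(
                f"only {len(vals)} reproducing {label}s with known birth years "
                f"(need >= {min_reproducers})"
            )
        out[label] = float(np.percentile(vals, percentile, method=method))
    pooled = float(np.percentile(ages["age"].to_numpy(dtype=float), percentile,
                                 method=method))
    return AdulthoodThreshold(female=out["female"], male=out["male"], pooled=pooled)


def _survives_to_adulthood(
    rec, thresholds: AdulthoodThreshold
) -> bool | None:
    """Whether an offspring's lifespan reaches its sex's adulthood threshold;
    None when its life history is incomplete."""
    if rec.lifespan is None:
        return None
    cut = {FEMALE: thresholds.female, MALE: thresholds.male}.get(
        rec.sex, thresholds.pooled
    )
    return rec.lifespan >= cut


def compute_proxies(
    ped: PedigreeTable,
    thresholds: AdulthoodThreshold,
    igc: Mapping[str, IGCSeries],
    statuses: Mapping[str, MigrationStatus] | None = None,
    cohort_width: int = 10,
) -> pd.DataFrame:
    """One row per focal with an IGC series: proxies, flags and final IGC.

    Rows are flagged, never dropped: ``eligible_core`` requires known birth
    and death years; ``eligible_grand`` additionally complete life histories
    for every offspring; ``eligible_model`` additionally known sex, making
    the row informative for all model predictors.  ``grandoffspring`` is 0
    for non-reproducers and missing (NaN) when any offspring is incomplete.
    """
    rows = []
    for focal, series in igc.items():
        rec = ped[focal]
        offspring = sorted(ped.child_index.get(focal, ()))
        lrs = len(offspring)
        lrs_sa = 0
        grand = 0
        offspring_complete = True
        for o in offspring:
            orec = ped[o]
            surv = _survives_to_adulthood(orec, thresholds)
            if surv is None:
                offspring_complete = False
            elif surv:
                lrs_sa += 1
            grand += len(ped.child_index.get(o, ()))
        lifespan = rec.lifespan
        parish = series.parish
        if statuses is not None and statuses.get(focal) is not None:
            parish = statuses[focal].home_parish or parish
        cohort = (
            f"{parish}:{(rec.birth_year // cohort_width) * cohort_width}"
            if rec.birth_year is not None
            else None
        )
        eligible_core = lifespan is not None
        eligible_grand = eligible_core and offspring_complete
        eligible_model = bool(
            eligible_grand and rec.sex in (FEMALE, MALE) and cohort is not None
        )
        rows.append(
            {
                "id": focal,
                "parish": parish,
                "sex": rec.sex,
                "birth_year": rec.birth_year,
                "birth_cohort": cohort,
                "lifespan": lifespan,
                "lrs": lrs,
                "lrs_sa": lrs_sa,
                "grandoffspring": grand if (offspring_complete or lrs == 0) else np.nan,
                "igc": series.final_year_value,
                "eligible_core": eligible_core,
                "eligible_grand": eligible_grand,
                "eligible_model": eligible_model,
            }
        )
    columns = ["id", "parish", "sex", "birth_year", "birth_cohort", "lifespan",
               "lrs", "lrs_sa", "grandoffspring", "igc", "eligible_core",
               "eligible_grand", "eligible_model"]
    df = pd.DataFrame(rows, columns=columns).sort_values("id").reset_index(drop=True)
    if not df.empty:
        logger.info(
            "proxies: %d focals, %d core-eligible, %d grand-eligible, %d model-eligible",
            len(df), int(df.eligible_core.sum()), int(df.eligible_grand.sum()),
            int(df.eligible_model.sum()),
        )
    return df


# -- lineage fates -------------------------------------------------------------


@dataclass
class LineageFate:
    focal: str
    n_descendants: int
    pct_descendants_reproduced: float
    pct_descendants_alive_unreproduced: float
    pct_failed: float
    pct_failed_by_emigration: float  # share of failures, not of all descendants
    extinct: bool


def _descendant_fate(
    ped: PedigreeTable,
    statuses: Mapping[str, MigrationStatus],
    desc_id: str,
    final_year: int,
) -> str:
    """Classify one descendant: 'reproduced' locally, 'alive' without having
    reproduced, 'emigrated' without local reproduction, or 'died'."""
    rec = ped[desc_id]
    st = statuses.get(desc_id)
    emigrated = st is not None and st.status == EMIGRANT
    has_offspring = bool(ped.child_index.get(desc_id))
    if has_offspring and not emigrated:
        return "reproduced"
    if has_offspring and emigrated:
        # offspring born before departure count as local reproduction
        dep = st.departure_year
        local = any(
            ped[c].birth_year is not None and dep is not None
            and ped[c].birth_year <= dep
            for c in ped.child_index.get(desc_id, ())
        )
        if local:
            return "reproduced"
    if emigrated:
        return "emigrated"
    alive = rec.death_year is None or rec.death_year >= final_year
    return "alive" if alive else "died"


def lineage_fates(
    ped: PedigreeTable,
    statuses: Mapping[str, MigrationStatus],
    igc: Mapping[str, IGCSeries],
    focals: Iterable[str],
    final_year: int,
) -> list[LineageFate]:
    """Per-focal descendant-fate percentages and the extinction flag
    (extinct = zero expected contribution to the final-year gene pool)."""
    out = []
    for focal in focals:
        desc = descendants(ped, focal)
        series = igc.get(focal)
        extinct = bool(series is not None and series.final_year_value == 0.0)
        if not desc:
            out.append(
                LineageFate(focal, 0, float("nan"), float("nan"), float("nan"),
                            float("nan"), extinct)
            )
            continue
        tallies = {"reproduced": 0, "alive": 0, "died": 0, "emigrated": 0}
        for d in desc:
            tallies[_descendant_fate(ped, statuses, d, final_year)] += 1
        n = len(desc)
        failed = tallies["died"] + tallies["emigrated"]
        out.append(
            LineageFate(
                focal=focal,
                n_descendants=n,
                pct_descendants_reproduced=100.0 * tallies["reproduced"] / n,
                pct_descendants_alive_unreproduced=100.0 * tallies["alive"] / n,
                pct_failed=100.0 * failed / n,
                pct_failed_by_emigration=(
                    100.0 * tallies["emigrated"] / failed if failed else float("nan")
                ),
                extinct=extinct,
            )
        )
    return out


def extinction_stages(
    proxies: pd.DataFrame, thresholds: AdulthoodThreshold
) -> dict[str, dict[str, float]]:
    """Life stage at which extinct lineages failed.

    Stages: died before reaching the (pooled) adulthood age; survived but
    left no offspring; had offspring but none survived to adulthood; had
    adult-surviving offspring but no grandoffspring; had grandoffspring yet
    the lineage still failed later.  Percentages are reported both
    conditional on extinction and over all focals.
    """
    ext = proxies[proxies["igc"] == 0.0]
    n_ext, n_all = len(ext), len(proxies)
    counts = {
        "died_before_adulthood": int((ext["lifespan"] < thresholds.pooled).sum()),
        "no_offspring": int(
            ((ext["lifespan"] >= thresholds.pooled) & (ext["lrs"] == 0)).sum()
        ),
        "no_adult_surviving_offspring": int(
            ((ext["lrs"] > 0) & (ext["lrs_sa"] == 0)).sum()
        ),
        "no_grandoffspring": int(
            ((ext["lrs_sa"] > 0) & (ext["grandoffspring"].fillna(0) == 0)).sum()
        ),
        "after_grandoffspring": int((ext["grandoffspring"].fillna(0) > 0).sum()),
    }
    return {
        "counts": counts,
        "pct_of_extinct": {
            k: (100.0 * v / n_ext if n_ext else float("nan"))
            for k, v in counts.items()
        },
        "pct_of_all": {
            k: (100.0 * v / n_all if n_all else float("nan"))
            for k, v in counts.items()
        },
    }


def offspring_mean_igc(
    ped: PedigreeTable,
    igc: Mapping[str, IGCSeries],
    focals: Iterable[str],
) -> pd.Series:
    """Per reproducing focal, the arithmetic mean of its offspring's own
    final-year IGC (offspring without an IGC series are skipped).
    Non-reproducers, and focals none of whose offspring have IGC, are
    excluded."""
    out = {}
    for focal in focals:
        vals = [
            igc[c].final_year_value
            for c in ped.child_index.get(focal, ())
            if c in igc
        ]
        if vals:
            out[focal] = float(np.mean(vals))
    return pd.Series(out, name="mean_offspring_igc", dtype=float)
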