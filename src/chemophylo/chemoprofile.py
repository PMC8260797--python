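"""Replicate-level chemical peak-table processing.

A peak table holds one row per (species, sex, mating status, replicate,
feature) with a non-negative detector area.  The standardization pipeline
mirrors common chemometric practice for cuticular-hydrocarbon data:

1. relative areas — each peak divided by the replicate's total area,
2. log transform with a pseudocount (absent features have relative area 0),
3. z-transform per feature across species.

Dimorphism calling: a compound is sex-specific for a species when it is
present (area above a detection floor) in at least ``presence_frac`` of the
replicates of one sex and in *zero* replicates of the other.  Species with
no sex-specific compound in either sex are monomorphic.  A male-specific
compound is "transferred" when it additionally appears on mated females
while being absent from virgin females.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

REQUIRED_COLUMNS = ("species", "sex", "mating", "replicate", "feature", "area")

MALE_SPECIFIC = "male_specific"
FEMALE_SPECIFIC = "female_specific"
SHARED = "shared"

__all__ = [
    "CompoundCatalog",
    "read_peak_table",
    "validate_peak_table",
    "standardize_profiles",
    "call_sex_specific",
    "call_transferred",
    "profile_correlation",
    "pca_scores",
]


@dataclass
class CompoundCatalog:
    """Compound-level specificity and transfer calls.

    Attributes
    ----------
    specificity : pd.Series
        feature -> {male_specific, female_specific, shared}.  A compound is
        sex-specific if it is sex-specific in at least one species; it can
        never be both male- and female-specific (calling is per species and
        a conflict raises).
    producing_species : dict
        feature -> frozenset of species for which the compound is specific
        to the corresponding sex.
    transferred : pd.Series or None
        feature -> bool, defined for male-specific compounds only; None
        before :func:`call_transferred` has run.
    calls : pd.DataFrame
        per-(species, feature) status table (long form) for auditing.
    dimorphic_species / monomorphic_species : list
        Species with / without at least one sex-specific compound.
    """

    specificity: pd.Series
    producing_species: dict[str, frozenset]
    calls: pd.DataFrame
    transferred: pd.Series | None = None
    dimorphic_species: list[str] = field(default_factory=list)
    monomorphic_species: list[str] = field(default_factory=list)

    def compounds(self, specificity: str) -> list[str]:
        return sorted(self.specificity.index[self.specificity == specificity])

    @property
    def male_specific(self) -> list[str]:
        return self.compounds(MALE_SPECIFIC)

    @property
    def female_specific(self) -> list[str]:
        return self.compounds(FEMALE_SPECIFIC)


def read_peak_table(path, sep: str = "\t") -> pd.DataFrame:
    pt = pd.read_csv(path, sep=sep)
    validate_peak_table(pt)
    return pt


def validate_peak_table(pt: pd.DataFrame, min_replicates: int = 5) -> None:
    """Check the PeakTable contract; raises ValueError on violation."""
    missing = [c for c in REQUIRED_COLUMNS if c not in pt.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if (pt["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    bad_sex = set(pt["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    bad_mat = set(pt["mating"]) - {"virgin", "mated"}
    if bad_mat:
        raise ValueError(f"unknown mating labels: {sorted(bad_mat)}")
    dup = pt.duplicated(["species", "sex", "mating", "replicate", "feature"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (species, sex, mating, replicate, "
            "feature) records"
        )
    reps = pt.groupby(["species", "sex"], observed=True)["replicate"].nunique()
    low = reps[reps < min_replicates]
    if not low.empty:
        warnings.warn(
            f"{len(low)} species-sex strata have fewer than "
            f"{min_replicates} replicates", stacklevel=2,
        )


# ---------------------------------------------------------------------
# standardization


def standardize_profiles(
    pt: pd.DataFrame,
    level: str = "species_mean",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Relative-area -> log -> z standardization of a peak table.

    Parameters
    ----------
    pt : peak table (already restricted to one sex if per-sex matrices are
        wanted; the transform itself is sex-agnostic).
    level : {"species_mean", "replicate"}
        "species_mean" averages relative areas over replicates per species
        before the log and z steps; "replicate" keeps one row per replicate
        (index = (species, sex, mating, replicate)).
    pseudocount : float, optional
        Added inside the log.  Default: half the smallest nonzero relative
        area in the table, which preserves ordering and avoids -inf.

    Returns
    -------
    DataFrame with species (or replicate multi-index) rows and feature
    columns, z-scored per feature; ``.attrs["transform"] == "z"``.
    """
    if level not in ("species_mean", "replicate"):
        raise ValueError(f"unknown level {level!r}")
    validate_peak_table(pt, min_replicates=0)

    wide = pt.pivot_table(
        index=["species", "sex", "mating", "replicate"],
        columns="feature",
        values="area",
        aggfunc="sum",
        fill_value=0.0,
    )
    totals = wide.sum(axis=1)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ValueError(
            f"replicates with zero total area: {list(zero.index[:5])}"
        )
    rel = wide.div(totals, axis=0)

    if level == "species_mean":
        rel = rel.groupby(level="species").mean()

    if pseudocount is None:
        nz = rel.values[rel.values > 0]
        if nz.size == 0:
            raise ValueError("peak table has no nonzero areas")
        pseudocount = 0.5 * float(nz.min())
    logged = np.log(rel + pseudocount)

    # z per feature across rows; zero-variance features -> 0 with warning
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    flat = sd[sd == 0]
    if not flat.empty:
        warnings.warn(
            f"{len(flat)} features constant across species; z set to 0",
            stacklevel=2,
        )
    z = (logged - mu).div(sd.replace(0.0, 1.0), axis=1)
    z.attrs["transform"] = "z"
    z.attrs["pseudocount"] = pseudocount
    z.attrs["level"] = level
    return z


# ---------------------------------------------------------------------
# dimorphism and transfer calling


def _presence(sub: pd.DataFrame, detection_floor: float) -> pd.DataFrame:
    """Per-(species, feature) fraction of replicates with area above floor.

    Replicates where a feature has no record count as absent."""
    n_reps = sub.groupby("species", observed=True)["replicate"].nunique()
    present = (
        sub[sub["area"] > detection_floor]
        .groupby(["species", "feature"], observed=True)["replicate"]
        .nunique()
        .rename("n_present")
        .reset_index()
    )
    present["frac"] = present.apply(
        lambda r: r["n_present"] / n_reps[r["species"]], axis=1
    ) if not present.empty else pd.Series(dtype=float)
    return present


def call_sex_specific(
    pt: pd.DataFrame,
    presence_frac: float = 0.5,
    detection_floor: float = 0.0,
) -> CompoundCatalog:
    """Call per-species sexually dimorphic compounds.

    Uses virgin individuals only (mated females may carry male compounds).
    A compound is specific to a sex for a species iff present in
    ``>= presence_frac`` of that sex's replicates and in zero replicates of
    the other sex.  Species without any sex-specific compound are
    monomorphic.  Species missing one sex entirely are skipped with a
    warning.
    """
    validate_peak_table(pt, min_replicates=0)
    virgin = pt[pt["mating"] == "virgin"]

    records = []
    producing: dict[str, set] = {}
    spec_level: dict[str, str] = {}
    dimorphic, monomorphic = [], []

    for species, sub in virgin.groupby("species", observed=True):
        sexes = set(sub["sex"])
        if sexes != {"male", "female"}:
            warnings.warn(
                f"species {species!r} lacks virgin replicates for "
                f"{sorted({'male', 'female'} - sexes)}; skipped",
                stacklevel=2,
            )
            continue
        found_specific = False
        for sex, other in (("male", "female"), ("female", "male")):
            own = _presence(sub[sub["sex"] == sex], detection_floor)
            other_present = set(
                map(
                    tuple,
                    _presence(sub[sub["sex"] == other], detection_floor)[
                        ["species", "feature"]
                    ].values,
                )
            )
            label = MALE_SPECIFIC if sex == "male" else FEMALE_SPECIFIC
            for _, row in own.iterrows():
                feature = row["feature"]
                if row["frac"] >= presence_frac and (species, feature) not in other_present:
                    records.append((species, feature, label))
                    prev = spec_level.get(feature)
                    if prev is not None and prev != label:
                        raise ValueError(
                            f"compound {feature!r} called {prev} and {label} "
                            "in different species"
                        )
                    spec_level[feature] = label
                    producing.setdefault(feature, set()).add(species)
                    found_specific = True
        (dimorphic if found_specific else monomorphic).append(species)

    all_features = sorted(set(pt["feature"]))
    specificity = pd.Series(
        {f: spec_level.get(f, SHARED) for f in all_features}, name="specificity"
    )
    calls = pd.DataFrame(records, columns=["species", "feature", "status"])
    return CompoundCatalog(
        specificity=specificity,
        producing_species={f: frozenset(s) for f, s in producing.items()},
        calls=calls,
        dimorphic_species=sorted(dimorphic),
        monomorphic_species=sorted(monomorphic),
    )


def call_transferred(
    pt: pd.DataFrame,
    catalog: CompoundCatalog,
    presence_frac: float = 0.5,
    detection_floor: float = 0.0,
) -> CompoundCatalog:
    """Flag male-specific compounds transferred to females during mating.

    A male-specific compound is transferred iff it is present on mated
    females (>= presence_frac of mated-female replicates of a producing
    species) while absent from all virgin females.  Female-specific
    compounds are never flagged.  Mutates and returns `catalog`.
    """
    mated_f = pt[(pt["sex"] == "female") & (pt["mating"] == "mated")]
    if mated_f.empty:
        raise ValueError("no mated-female records in peak table")
    virgin_f = pt[(pt["sex"] == "female") & (pt["mating"] == "virgin")]

    male_compounds = catalog.male_specific
    transferred = {}
    mated_pres = _presence(mated_f, detection_floor)
    virgin_present = set(
        map(tuple, _presence(virgin_f, detection_floor)[["species", "feature"]].values)
    )
    for feature in male_compounds:
        flag = False
        for species in catalog.producing_species.get(feature, ()):
            hit = mated_pres[
                (mated_pres["species"] == species)
                & (mated_pres["feature"] == feature)
            ]
            frac = float(hit["frac"].iloc[0]) if not hit.empty else 0.0
            if frac >= presence_frac and (species, feature) not in virgin_present:
                flag = True
                break
        transferred[feature] = flag
    catalog.transferred = pd.Series(transferred, name="transferred", dtype=bool)
    return catalog


# ---------------------------------------------------------------------
# ordination & correlation


def profile_correlation(tm: pd.DataFrame) -> pd.DataFrame:
    """Species-by-species Pearson correlation of chemical profiles.

    Rows of `tm` are species, columns features.  Pairwise-complete over
    finite values; diagonal set to exactly 1; zero-variance species get NaN
    rows/columns with a warning.
    """
    if tm.shape[1] < 2:
        raise ValueError("need >= 2 features per species for correlation")
    sd = tm.std(axis=1, ddof=0)
    degenerate = sd.index[sd == 0]
    if len(degenerate):
        warnings.warn(
            f"species with zero-variance profiles: {list(degenerate)}; "
            "correlations undefined (NaN)", stacklevel=2,
        )
    corr = tm.T.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    for s in degenerate:
        corr.loc[s, s] = np.nan
    return corr


def pca_scores(tm: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal-component scores of centered profiles.

    Returns (scores DataFrame indexed like tm with columns PC1..PCk,
    explained-variance fractions).  ``k`` must not exceed the data rank.
    """
    X = np.asarray(tm, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=tm.index, columns=cols),
        pca.explained_variance_ratio_,
    )
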