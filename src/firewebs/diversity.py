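"""Hill-number diversity and sample-coverage estimation.

Hill numbers of order q give the effective number of species: q=0 is
richness, q=1 the exponential of Shannon entropy (number of common
species), q=2 the inverse Simpson concentration (number of dominant
species).  Sample coverage — the estimated fraction of community
abundance represented by the species already sampled — comes from the
singleton/doubleton estimator

    C_hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)].

Confidence intervals for grouped coverage are percentile bootstrap over
individuals (the analytic variance is not exposed here by design).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _clean(counts) -> np.ndarray:
    arr = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts,
                     dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0 or arr.sum() == 0:
        raise ValueError("abundance vector is empty")
    return arr


def hill_number(counts, q: float) -> float:
    """Effective number of species of order q >= 0."""
    if q < 0:
        raise ValueError("q must be non-negative")
    arr = _clean(counts)
    p = arr / arr.sum()
    if q == 0:
        return float(arr.size)
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def sample_coverage(counts) -> float:
    """Singleton/doubleton sample-coverage estimate, in [0, 1]."""
    arr = _clean(counts)
    n = arr.sum()
    f1 = float((arr == 1).sum())
    f2 = float((arr == 2).sum())
    if f1 == 0:
        return 1.0
    if n <= 1:
        return 0.0
    denom = (n - 1) * f1 + 2 * f2
    cov = 1.0 - (f1 / n) * ((n - 1) * f1 / denom)
    return float(min(max(cov, 0.0), 1.0))


def bootstrap_coverage_ci(
    counts,
    reps: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for sample coverage, resampling individuals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _clean(counts).astype(int)
    n = int(arr.sum())
    p = arr / n
    stats = np.empty(reps)
    for i in range(reps):
        resample = rng.multinomial(n, p)
        stats[i] = sample_coverage(resample[resample > 0])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def grouped_validation(
    survey_tables: Mapping[str, pd.DataFrame],
    method_groups: Mapping[str, Sequence[str]],
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage/diversity table per taxonomic group x treatment.

    Sampling methods with overlapping species records are pooled into
    named groups; per group and treatment the table reports individuals,
    observed richness, sample coverage and a bootstrap CI — the shape of a
    standard technical-validation table.

    ``survey_tables`` maps method -> DataFrame with columns node_id (or
    species_id), treatment, count.  ``method_groups`` maps group label ->
    list of methods; every method must belong to a group.
    """
    grouped_methods = {m for methods in method_groups.values() for m in methods}
    orphan = sorted(set(survey_tables) - grouped_methods)
    if orphan:
        raise ValueError(f"methods assigned to no validation group: {orphan}")

    rng = np.random.default_rng(seed)
    rows = []
    for group_label in sorted(method_groups):
        frames = [
            survey_tables[m] for m in method_groups[group_label] if m in survey_tables
        ]
        if not frames:
            continue
        pooled = pd.concat(frames, ignore_index=True)
        id_col = "node_id" if "node_id" in pooled.columns else "species_id"
        # diversity is tallied over species, not ontogenetic stages
        pooled["species"] = pooled[id_col].astype(str).str.split(".").str[0]
        for treatment, sub in pooled.groupby("treatment", sort=True):
            counts = sub.groupby("species")["count"].sum()
            counts = counts[counts > 0]
            if counts.empty:
                continue
            cov = sample_coverage(counts)
            lo, hi = bootstrap_coverage_ci(counts, reps=bootstrap_reps, seed=rng)
            rows.append(
                {
                    "taxonomic_group": group_label,
                    "treatment": treatment,
                    "individuals": int(counts.sum()),
                    "observed_richness": int(counts.size),
                    "sample_coverage": cov,
                    "lower_cl": lo,
                    "upper_cl": hi,
                    "hill_q0": hill_number(counts, 0),
                    "hill_q1": hill_number(counts, 1),
                    "hill_q2": hill_number(counts, 2),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["taxonomic_group", "treatment", "individuals", "observed_richness",
                 "sample_coverage", "lower_cl", "upper_cl", "hill_q0", "hill_q1",
                 "hill_q2"],
    )
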