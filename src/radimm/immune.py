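"""Flow-cytometry population frequencies and the BMDM/MG ratio.

Each specimen carries four gated frequencies following the cytometry
hierarchy: leukocytes (CD45+) as % of live cells, myeloid (CD33+) as % of
leukocytes, and the two macrophage subsets as % of myeloid — BMDM
(HLA-DR+/CD49d+, blood-derived, immunosuppressive) and MG
(HLA-DR+/CD49d−, brain-resident). The BMDM/MG ratio condenses the two
subsets into one index of blood-macrophage recruitment: higher values
mark a more immunosuppressive, centrally located microenvironment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import SITES
from .stats import kruskal_wallis, mann_whitney

FREQ_COLUMNS = ("pct_leukocytes", "pct_myeloid", "pct_bmdm", "pct_mg")
POPULATIONS = ("leukocytes", "myeloid", "BMDM", "MG")


class SampleValidationError(ValueError):
    """Raised for frequencies outside [0, 100] or gating violations."""


@dataclass(frozen=True)
class ImmunoSample:
    """One specimen's gated population frequencies plus its sampling site."""

    subject_id: str
    site: str
    pct_leukocytes: float
    pct_myeloid: float
    pct_bmdm: float
    pct_mg: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise SampleValidationError(f"unknown site {self.site!r}; expected one of {SITES}")
        for name in FREQ_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 100.0:
                raise SampleValidationError(f"{name}={v!r} outside [0, 100] (subject {self.subject_id})")
        if self.pct_bmdm + self.pct_mg > 100.0 + 1e-9:
            raise SampleValidationError(
                f"pct_bmdm + pct_mg = {self.pct_bmdm + self.pct_mg:.3f} > 100 (subject {self.subject_id})"
            )


def read_samples(path: str | Path) -> list[ImmunoSample]:
    """Read and validate a specimen table (CSV, one row per specimen)."""
    df = pd.read_csv(path)
    required = {"subject_id", "site", *FREQ_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise SampleValidationError(f"{path}: missing column(s) {sorted(missing)}")
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                ImmunoSample(
                    subject_id=str(row["subject_id"]),
                    site=str(row["site"]),
                    **{c: float(row[c]) for c in FREQ_COLUMNS},
                )
            )
        except SampleValidationError as e:
            raise SampleValidationError(f"{path}, row {i}: {e}") from e
    return samples


def samples_to_frame(samples: list[ImmunoSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "site": s.site,
                **{c: getattr(s, c) for c in FREQ_COLUMNS},
            }
            for s in samples
        ]
    )


def bmdm_mg_ratio(pct_bmdm: float, pct_mg: float) -> float | None:
    """BMDM/MG ratio; ``None`` (undefined) when the MG frequency is zero.

    The undefined case is deliberately neither 0 nor infinity: specimens
    without detectable MG carry no ratio and are excluded downstream.
    """
    for name, v in (("pct_bmdm", pct_bmdm), ("pct_mg", pct_mg)):
        if not np.isfinite(v) or not 0.0 <= v <= 100.0:
            raise SampleValidationError(f"{name}={v!r} outside [0, 100]")
    if pct_mg == 0.0:
        return None
    return pct_bmdm / pct_mg


def aggregate_subject_site(samples: list[ImmunoSample]) -> pd.DataFrame:
    """Average frequencies within (subject, site), then take the ratio.

    The order matters: raw frequencies are averaged first and the ratio is
    computed from the averaged frequencies (mean-of-frequencies-then-ratio,
    not mean-of-ratios). Columns: subject_id, site, the four averaged
    frequencies, ratio, n_samples_averaged, defined.
    """
    if not samples:
        return pd.DataFrame(
            columns=["subject_id", "site", *FREQ_COLUMNS, "ratio", "n_samples_averaged", "defined"]
        )
    df = samples_to_frame(samples)
    agg = (
        df.groupby(["subject_id", "site"], sort=True)
        .agg(**{c: (c, "mean") for c in FREQ_COLUMNS}, n_samples_averaged=("site", "size"))
        .reset_index()
    )
    ratios = [bmdm_mg_ratio(b, g) for b, g in zip(agg["pct_bmdm"], agg["pct_mg"])]
    agg["defined"] = [r is not None for r in ratios]
    agg["ratio"] = [np.nan if r is None else r for r in ratios]
    return agg


def compare_sites(
    values_by_site: dict[str, np.ndarray],
    variable: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal–Wallis across all sites plus all pairwise Mann–Whitney tests.

    Sites with fewer than 2 values are skipped with a warning and their
    pairwise rows omitted. Returns one row per test: variable, test,
    site_a, site_b ('' for the omnibus test), statistic, p, n_a, n_b,
    significant (at ``alpha``).
    """
    usable = {}
    for site, vals in values_by_site.items():
        vals = np.asarray(vals, dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            warnings.warn(f"{variable}: site {site!r} has < 2 values; skipped", stacklevel=2)
            continue
        usable[site] = vals
    rows = []
    if len(usable) >= 2:
        h, p = kruskal_wallis(list(usable.values()))
        rows.append(
            {
                "variable": variable,
                "test": "kruskal_wallis",
                "site_a": "|".join(usable),
                "site_b": "",
                "statistic": h,
                "p": p,
                "n_a": int(sum(v.size for v in usable.values())),
                "n_b": 0,
                "significant": p < alpha,
            }
        )
        for a, b in itertools.combinations(usable, 2):
            u, p = mann_whitney(usable[a], usable[b])
            rows.append(
                {
                    "variable": variable,
                    "test": "mann_whitney",
                    "site_a": a,
                    "site_b": b,
                    "statistic": u,
                    "p": p,
                    "n_a": int(usable[a].size),
                    "n_b": int(usable[b].size),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def site_comparison_report(aggregated: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Compare every immune variable and the ratio across sampling sites.

    Runs ``compare_sites`` on the four population frequencies and on the
    BMDM/MG ratio (defined values only), over subject-site aggregates.
    """
    reports = []
    for col, label in [*((c, c) for c in FREQ_COLUMNS), ("ratio", "bmdm_mg_ratio")]:
        sub = aggregated if col != "ratio" else aggregated[aggregated["defined"]]
        by_site = {site: sub.loc[sub["site"] == site, col].to_numpy() for site in SITES}
        by_site = {s: v for s, v in by_site.items() if v.size > 0}
        if by_site:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports.append(compare_sites(by_site, variable=label, alpha=alpha))
    return pd.concat([r for r in reports if not r.empty], ignore_index=True) if reports else pd.DataFrame()
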