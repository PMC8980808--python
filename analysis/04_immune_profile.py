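#!/usr/bin/env python
"""Immune-population gradients and the BMDM/MG ratio across sampling sites.

Aggregates specimens per subject and site (frequencies averaged before the
ratio), reports site medians, runs Kruskal-Wallis and pairwise
Mann-Whitney comparisons for every population and for the BMDM/MG ratio,
and fits the multi-group PCA of the four immune variables by site.
Writes results/ratios.csv, results/site_tests.tsv and
results/immune_loading_similarity.tsv.
"""

from pathlib import Path

import pandas as pd

from radimm.constants import SITES
from radimm.immune import FREQ_COLUMNS, aggregate_subject_site, read_samples, site_comparison_report
from radimm.stats import loading_similarity, multigroup_pca

OUT = Path("results")


def main() -> None:
    samples = read_samples(OUT / "cohort" / "immune_samples.csv")
    agg = aggregate_subject_site(samples)
    agg.to_csv(OUT / "ratios.csv", index=False, float_format="%.10g")

    med = agg.groupby("site")[[*FREQ_COLUMNS, "ratio"]].median().loc[list(SITES)]
    print("site medians (leukocytes/myeloid as % of parent; BMDM/MG as % of myeloid):")
    print(med.round(2).to_string())
    print(f"\nundefined ratios (MG = 0): {int((~agg['defined']).sum())}")

    report = site_comparison_report(agg)
    report.to_csv(OUT / "site_tests.tsv", sep="\t", index=False, float_format="%.6g")
    sig = report[report["significant"]]
    print(f"{len(sig)}/{len(report)} site contrasts significant at 0.05, including:")
    for _, row in sig[sig["test"] == "mann_whitney"].head(6).iterrows():
        print(f"  {row['variable']}: {row['site_a']} vs {row['site_b']} p={row['p']:.2g}")

    # multi-group PCA of the 4 immune variables: per-site models vs all sites
    tables = {
        site: agg[agg["site"] == site].set_index("subject_id")[list(FREQ_COLUMNS)]
        for site in SITES
    }
    group_models, pooled = multigroup_pca(tables)
    rows = []
    names = [*group_models, "all"]
    models = {**group_models, "all": pooled}
    for a in names:
        for b in names:
            rows.append({"a": a, "b": b,
                         "similarity": loading_similarity(models[a].loadings, models[b].loadings, k=2).value})
    sim = pd.DataFrame(rows).pivot(index="a", columns="b", values="similarity")
    sim.to_csv(OUT / "immune_loading_similarity.tsv", sep="\t", float_format="%.4g")
    print("\nimmune loading similarity across sites (first two components):")
    print(sim.round(2).to_string())


if __name__ == "__main__":
    main()
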