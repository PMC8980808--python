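#!/usr/bin/env python
"""Per-tissue and aggregate PCA of the imaging features.

Fits a PCA on the 17 z-scored features of each lesion compartment and on
all 68 features jointly, reports how many components reach 80% of the
variance, correlates the first four PC score sets across tissues, and
quantifies cross-tissue loading agreement with the structural similarity
index. Writes PCA models (JSON), scores, the similarity matrix and the
cross-correlation summary under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from radimm.constants import TISSUES
from radimm.pipeline import imaging_pca_models, loading_similarity_matrix
from radimm.stats import pc_cross_correlation

OUT = Path("results")


def main() -> None:
    features = pd.read_csv(OUT / "features.csv", index_col="subject_id")
    models, n80 = imaging_pca_models(features)

    print("components needed for 80% of variance:", n80)
    pc1 = {name: round(float(m.explained[0]) * 100, 1) for name, m in models.items()}
    print("variance explained by PC1 (%):", pc1)

    for name, model in models.items():
        payload = {
            "feature_names": model.feature_names,
            "loadings": model.loadings.to_numpy().tolist(),
            "explained": model.explained.tolist(),
            "n_components_80": n80[name],
            "n_used": model.n_used,
        }
        (OUT / f"pca_{name}.json").write_text(json.dumps(payload, indent=1))
        model.scores.to_csv(OUT / f"scores_{name}.csv", index_label="subject_id", float_format="%.10g")

    sim = loading_similarity_matrix(models, n80)
    sim.to_csv(OUT / "loading_similarity.tsv", sep="\t", float_format="%.4g")
    off = sim.to_numpy()[~np.eye(4, dtype=bool)]
    print(f"cross-tissue loading similarity: {off.min():.2f} - {off.max():.2f} "
          "(1 = identical loading structure)")

    cross = pc_cross_correlation({t: models[t] for t in TISSUES}, k=4)
    rows = []
    for (a, b), mat in cross.items():
        if a < b:
            rows.append({"tissue_a": a, "tissue_b": b,
                         "pc1_pc1_r": float(mat.iloc[0, 0]),
                         "max_abs_offdiag": float(np.nanmax(np.abs(mat.to_numpy() - np.diag(np.diag(mat))))) })
    pd.DataFrame(rows).to_csv(OUT / "pc_cross_correlation.csv", index=False, float_format="%.4g")
    print(f"models, scores, similarity and cross-correlations written to {OUT}/")


if __name__ == "__main__":
    main()
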