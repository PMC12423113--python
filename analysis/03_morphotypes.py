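"""Morphotype delineation: PCA of size-adjusted measurements, silhouette
choice of k, k-means clustering, and between-cluster testing.

Writes cluster assignments, the silhouette table, and the MANOVA /
Bonferroni-corrected post hoc report.
"""

from pathlib import Path

import pandas as pd

from codniche.morphometry import MEASUREMENTS
from codniche.morphotyping import (
    assumption_checks,
    kmeans_cluster,
    manova_pillai,
    measurement_pca,
    posthoc_welch,
    select_k_silhouette,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "morphotypes"
ADJ = tuple(f"{m}_adj" for m in MEASUREMENTS)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ROOT / "morphometrics" / "measurements.csv")
    pca = measurement_pca(table, ADJ)
    print("measurement PCA: PC1 {:.1f}%, PC2 {:.1f}%".format(
        *pca.percent_variance[:2]))

    scores = pca.scores[:, :2]
    k, sil = select_k_silhouette(scores, (2, 3, 4, 5), seed=0)
    km = kmeans_cluster(scores, k, seed=0)
    sil.to_csv(OUT / "silhouette_by_k.csv", index=False)
    pd.DataFrame({"specimen_id": table["specimen_id"],
                  "cluster": km.assignments}
                 ).to_csv(OUT / "morphotype_assignments.csv", index=False)
    sizes = pd.Series(km.assignments).value_counts().sort_index()
    print(f"silhouette selects k = {k}; cluster sizes: {dict(sizes)}")

    checks = assumption_checks(table, ADJ, km.assignments)
    checks.to_csv(OUT / "assumption_checks.csv", index=False)
    manova = manova_pillai(table, ADJ, km.assignments)
    print(f"MANOVA Pillai V = {manova.statistic:.3f}, "
          f"F = {manova.f_statistic:.2f}, p = {manova.p_value:.3g}")
    posthoc = posthoc_welch(table, ADJ, km.assignments, m_tests=9)
    posthoc.rows.to_csv(OUT / "posthoc_tests.csv", index=False)
    sig = posthoc.rows[posthoc.rows["significant"]]["measurement"]
    print(f"post hoc (Bonferroni alpha = {posthoc.adjusted_alpha:.4f}): "
          f"{len(sig)}/9 measurements differ: {', '.join(sig)}")


if __name__ == "__main__":
    main()
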