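"""Pan-cancer co-expression survey of the synthetic study.

Correlates every gene with the focal gene inside each cohort, standardizes
per cohort, takes the per-gene median z, and checks that the planted
regulators surface at the extremes. Writes results/coexpression.tsv.

    python analysis/02_coexpression_survey.py
"""

from regscan import io
from regscan.coexpression import pan_cancer_median, spearman_to_focal, z_transform
from regscan.pipeline import _load_cohorts

from _study import RESULTS, STUDY_DIR


def main() -> None:
    cohorts = _load_cohorts(str(STUDY_DIR / "cohorts"))
    zs = [z_transform(spearman_to_focal(c, "FOCAL")) for c in cohorts]
    score = pan_cancer_median(zs)
    out = RESULTS / "coexpression.tsv"
    score.table.to_csv(out, sep="\t", index_label="gene", float_format=io.FLOAT_FORMAT)

    truth = io.read_json(STUDY_DIR / "truth.json")
    median = score.median_z
    print(f"scored {len(median)} genes across {len(cohorts)} cohorts -> {out}")
    print("top 5 positive correlates:")
    print(median.nlargest(5).round(2).to_string())
    print("top 5 negative correlates:")
    print(median.nsmallest(5).round(2).to_string())
    planted = set(truth["regulators"])
    top = set(median.abs().nlargest(len(planted)).index)
    print(f"planted regulators recovered in top-{len(planted)} |median z|: "
          f"{len(planted & top)}/{len(planted)}")


if __name__ == "__main__":
    main()
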