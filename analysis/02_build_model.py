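"""Stage 1: build and evaluate the residual-disease model on the phantom
hysterectomy cohort.

Runs VOI construction, feature extraction on T2WI and ADC, the
ICC-repeatability filter, Boruta selection on the training half, both
random-forest models and the positive-margin baseline, and the DeLong AUC
comparisons. Writes the metric panel (model x cohort), the ICC report and
the Boruta statuses to results/; the full cases x features table goes to
scratch/ (it is bulky and fully regenerable).

Run: python analysis/02_build_model.py [--seed 0]
"""

import argparse
import json
import warnings
from pathlib import Path

from marginrad.pipeline import StudyConfig, run_stage1

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    cfg = StudyConfig(seed=args.seed)
    report = run_stage1(cfg)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)

    report.metrics.to_csv(results / "model_metrics.csv", index=False)
    report.icc.table.to_csv(results / "icc_report.csv", index_label="feature")
    report.boruta.status.rename("status").to_csv(results / "boruta_status.csv", index_label="feature")
    report._features.to_csv(scratch / "feature_table.csv", index_label="case_id")
    (results / "delong.json").write_text(json.dumps(report.delong, indent=2))

    kept = report.kept_by_sequence
    print(f"{report.n_features_per_sequence} features per sequence; ICC>0.75 kept "
          f"{report.n_repeatable} ({kept['T2WI']} T2WI + {kept['ADC']} ADC); "
          f"Boruta confirmed {report.n_confirmed} all-relevant features")
    m = report.metrics.set_index(["model", "cohort"])["auc"]
    line = ", ".join(f"{mod} {m[(mod, 'test')]:.3f}" for mod in ("RF", "Boruta", "PM")
                     if (mod, "test") in m.index)
    print(f"test AUC: {line}")
    if "boruta_vs_rf" in report.delong:
        print(f"DeLong Boruta vs RF: p = {report.delong['boruta_vs_rf']['p']:.3f}; "
              f"Boruta vs positive margin: p = {report.delong['boruta_vs_pm']['p']:.4f}")
    print(f"tables -> {results}")


if __name__ == "__main__":
    main()
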