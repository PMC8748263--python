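"""Manual cross-validation of the aging-curve fitter against mgcv::gamm.

Generates a shared synthetic outcome table, fits it with this package, and
writes both the data and the fitted curve so `scripts/crosscheck_mgcv.R` can
fit the same model in R and compare.  Agreement target: curve RMS difference
within 5% of the outcome SD.  Run manually:

    python scripts/crosscheck_gamm.py --out scratch/xcheck
    Rscript scripts/crosscheck_mgcv.R scratch/xcheck
"""

import argparse
from pathlib import Path

import numpy as np

from csa_aging.gamm import fit_gamm, predict_curve
from csa_aging.synthetic import CohortSpec, generate_cohort, simulate_outcome_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/xcheck"))
    parser.add_argument("--seed", type=int, default=5)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    cohort = generate_cohort(CohortSpec(), rng)
    df = simulate_outcome_table(
        cohort, lambda a: 2.0 + 0.05 * a + 0.2 * np.maximum(0, a - 72), 0.3, 0.15, rng
    )
    df["sex01"] = (df["sex"] == "male").astype(int)
    df.to_csv(args.out / "data.csv", index=False)

    fit = fit_gamm(df)
    curve = predict_curve(fit, np.linspace(df["age"].min(), df["age"].max(), 50))
    curve.to_csv(args.out / "py_curve.csv", index=False)
    print(
        f"python fit: edf={fit.edf_smooth:.3f} s(age).p={fit.smooth_p:.3g} "
        f"sigma2_b={fit.sigma2_b:.4f} sigma2_e={fit.sigma2_e:.4f}"
    )
    print(fit.coef_table.round(4))
    print(f"outcome SD: {df['value'].std():.4f}")


if __name__ == "__main__":
    main()
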