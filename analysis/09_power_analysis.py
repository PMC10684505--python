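"""A priori sample-size computation for the remote study: within-factor
repeated-measures ANOVA (2 medication groups x 2 timepoints, Cohen's
f = 0.25, alpha = 0.01, target power 0.95, repeated-measures correlation
0.5), plus the equal-proportion control extrapolation.
"""

import json

from _common import SURVEY_DIR
from glp1alc.inference import extrapolate_controls, power_rm_anova


def main() -> None:
    n_med, achieved = power_rm_anova(
        f=0.25, alpha=0.01, power=0.95, k_groups=2, m_measurements=2, rho=0.5, eps=1.0
    )
    total = extrapolate_controls(n_med, 2)
    SURVEY_DIR.mkdir(parents=True, exist_ok=True)
    (SURVEY_DIR / "power_analysis.json").write_text(
        json.dumps(
            {
                "medication_participants": n_med,
                "achieved_power": achieved,
                "total_with_controls": total,
            },
            indent=2,
        )
    )
    print(f"medication participants required: {n_med} (achieved power {achieved:.3f})")
    print(f"total with an equal-proportion control group: {total}")


if __name__ == "__main__":
    main()
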