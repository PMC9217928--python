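#!/usr/bin/env python
"""Sex-ratio tests against the expected 1:1 binomial.

Exact one-sided tests (female-deficiency direction) for the published D56
and D105 group compositions: the female deficit at D105 is not significant
among AI controls but highly significant in the IVP group, the pattern
expected if female fetuses are preferentially lost after D56.
"""

import json
from pathlib import Path

from loscreen.phenotyping import sex_ratio_test

OUT = Path(__file__).resolve().parent.parent / "results" / "phenotyping"

# (day, group): (n_female, n_total) from the collection summaries
COMPOSITIONS = {
    ("D56", "AI"): (6, 14),
    ("D56", "IVP"): (22, 43),
    ("D105", "AI"): (4, 12),
    ("D105", "IVP"): (13, 46),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for (day, group), (n_f, n_t) in COMPOSITIONS.items():
        res = sex_ratio_test(n_f, n_t)
        summary[f"{day}:{group}"] = {
            "n_female": n_f, "n_total": n_t, "p_value": round(res.p_value, 5),
        }
        print(f"{day} {group}: {n_f}/{n_t} female, one-sided exact p = {res.p_value:.4f}")
    (OUT / "sex_ratio.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
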