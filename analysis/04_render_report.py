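#!/usr/bin/env python
"""Render trajectory figures and summary tables from the cohort result JSON."""

import json
from pathlib import Path

from prostate_qmri.reporting import render_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    result = json.loads((ROOT / "cohort_result.json").read_text())
    for path in render_report(result, ROOT / "report"):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
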