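#!/usr/bin/env python
"""Consolidate the stage outputs under results/ into one JSON report."""

import json
from pathlib import Path

from wormquant.report import build_report

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    stages = {}
    for p in sorted(RESULTS.glob("*.json")):
        if p.name == "report.json":
            continue
        stages[p.stem] = json.loads(p.read_text())
    if not stages:
        raise SystemExit("no stage JSON under results/; run drivers 02-05 first")
    build_report(stages, out_path=RESULTS / "report.json")
    print(f"consolidated {len(stages)} stage file(s) into results/report.json")


if __name__ == "__main__":
    main()
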