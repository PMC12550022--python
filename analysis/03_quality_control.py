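#!/usr/bin/env python
"""Apply the worker/trial exclusion rules to the simulated raw choices.

Reads results/choices_raw.tsv (from 02), excludes workers with repeated
fast sets or position-deterministic sets, drops trials under 900 ms, and
reports retained fraction and choice consistency over repeated triplets.
Writes the retained table and a JSON report.
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sposekit import filter_trials, qc_report
from sposekit.io import read_choices, write_choices

OUT = Path(__file__).resolve().parents[1] / "results"

choices = read_choices(OUT / "choices_raw.tsv")
report = qc_report(choices)
retained, _ = filter_trials(choices, report.excluded_workers)

print(f"workers excluded: {[(e.worker_id, e.reason) for e in report.excluded_workers]}")
print(f"retained {report.retained_trials:,} / {report.total_trials:,} trials "
      f"({report.retained_fraction * 100:.1f}%)")
print(f"choice consistency on repeated triplets: {report.consistency * 100:.2f}% "
      f"(chance 33.3%)")

write_choices(retained, OUT / "choices_retained.tsv")
payload = dataclasses.asdict(report)
payload["excluded_workers"] = [dataclasses.asdict(e)
                               for e in report.excluded_workers]
(OUT / "qc_report.json").write_text(json.dumps(payload, indent=2))
print(f"wrote {OUT / 'choices_retained.tsv'} and qc_report.json")
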