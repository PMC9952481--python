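"""Write a study to JSON, read it back, and export every pipeline matrix.

Study files carry the whole decision problem — alternatives, the parameter
space with disjoint sub-parameter sets, per-expert CIFN opinions (arrays
[at, bt, af, bf], phases as fractions of 2*pi), and patient intervals.
``write_matrices`` dumps one CSV per pipeline stage plus a JSON report.
"""

import tempfile
from pathlib import Path

from fphss import brain_tumour_study, read_study, run_pmbsa, write_matrices, write_study

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    path = write_study(brain_tumour_study(), tmp / "study.json")
    print(f"wrote {path.name} ({path.stat().st_size} bytes)")

    study = read_study(path)  # full schema + grade validation on load
    result = run_pmbsa(study)

    files = write_matrices(result, tmp / "out")
    for f in files:
        print(f"  {f.name}")

    # the core CSV holds the aggregated evidence each score averages over
    print("\ncore.csv, first data line:")
    print((tmp / "out" / "core.csv").read_text().splitlines()[1][:80], "...")
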