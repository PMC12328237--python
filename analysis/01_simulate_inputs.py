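#!/usr/bin/env python
"""Generate the synthetic inputs every downstream analysis consumes.

Writes a complete fixture directory (counts, junction tables, allele
reads, ligand-receptor pair table, cross-species profiles) plus the
ground-truth JSON under results/fixture/.
"""

from pathlib import Path

from click.testing import CliRunner

from atlasstats.cli import main

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"

if __name__ == "__main__":
    result = CliRunner().invoke(main, ["simulate", "--seed", "1", "--out", str(OUT)])
    print(result.output, end="")
    if result.exit_code:
        raise SystemExit(result.exit_code)
    print("files:", ", ".join(sorted(p.name for p in OUT.iterdir())))
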