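#!/usr/bin/env python
"""Generate the five synthetic study conditions and write them to disk.

Emits, for each preset, a FASTA genome, a GFF3 gene annotation, one
Bismark CX report per group x replicate, the planted-truth tables and
the exact config — everything the downstream steps consume.  Output
goes under scratch/sim/<preset>/ (bulky, regenerable); the presets are
deterministic under the recorded seed.
"""

import subprocess
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
PRESETS = ("context", "feature", "global", "dmr-null", "dmr-alt")
SEED = 42


def main() -> None:
    for name in PRESETS:
        out = ROOT / "scratch" / "sim" / name
        print(f"[01] simulating preset {name!r} (seed {SEED}) -> {out}")
        subprocess.run(
            [sys.executable, "-m", "bsmeth.cli", "simulate", "--preset", name,
             "--seed", str(SEED), "--out-dir", str(out)],
            check=True,
        )
    print("[01] done: five presets written; CX reports are the pipeline inputs")


if __name__ == "__main__":
    main()
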