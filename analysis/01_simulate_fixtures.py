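#!/usr/bin/env python
"""Generate the synthetic input set for the downstream analyses.

Emits the 6-mass calibration series and the 4-ratio PEGylation series as
JCAMP-DX, one inversion-recovery table per reference peak, and the pipeline
manifest, under scratch/fixtures (spectra are large; only derived tables go
to results/).
"""

import argparse
from pathlib import Path

from psiqnmr import make_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "fixtures")
    args = parser.parse_args()
    manifest = make_fixtures(args.seed, args.out)
    files = sorted(p.name for p in args.out.iterdir())
    print(f"wrote {len(files)} files to {args.out}:")
    for name in files:
        print(f"  {name}")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
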