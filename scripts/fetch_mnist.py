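#!/usr/bin/env python
"""Download MNIST or Fashion MNIST IDX files (requires network access).

The core library never downloads anything; this convenience script fetches
the standard IDX pairs so they can be fed to ``tracebench.read_idx`` or a
``dataset: {kind: idx, ...}`` sweep config.

Usage: python scripts/fetch_mnist.py [--fashion] [--out-dir data/mnist]
"""

from __future__ import annotations

import argparse
import gzip
import urllib.request
from pathlib import Path

MIRRORS = {
    "mnist": "https://ossci-datasets.s3.amazonaws.com/mnist/",
    "fashion": "http://fashion-mnist.s3-website.eu-central-1.amazonaws.com/",
}
FILES = [
    "train-images-idx3-ubyte.gz",
    "train-labels-idx1-ubyte.gz",
    "t10k-images-idx3-ubyte.gz",
    "t10k-labels-idx1-ubyte.gz",
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fashion", action="store_true", help="fetch Fashion MNIST instead")
    ap.add_argument("--out-dir", type=Path, default=Path("data/mnist"))
    args = ap.parse_args()
    base = MIRRORS["fashion" if args.fashion else "mnist"]
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for name in FILES:
        target = args.out_dir / name.removesuffix(".gz")
        if target.exists():
            print(f"{target} already present")
            continue
        print(f"fetching {base}{name} ...")
        with urllib.request.urlopen(base + name) as resp:
            target.write_bytes(gzip.decompress(resp.read()))
        print(f"wrote {target} ({target.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
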