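"""Regenerate the fitted lobe-parameter cache shipped with the package.

Runs the signed-lobe and absolute-lobe fits for every supported p shell
and writes src/lobehf/basisdata/lobe-params-v1.json.  Run from the repo
root after changing the fitting protocol or the STO-6G reference data.
"""

import json
import sys
from pathlib import Path

root = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(root / "src"))

import lobehf.basis as basis  # noqa: E402

P_SHELLS = [("C", "2p"), ("N", "2p"), ("O", "2p"),
            ("P", "2p"), ("P", "3p"), ("S", "2p"), ("S", "3p")]


def main():
    basis._lobe_cache = {}
    for el, shell in P_SHELLS:
        fit, ab = basis.get_lobe_parameters(el, shell)
        print(f"{el} {shell}: signed rel L2 {fit.rel_l2_error:.4f} "
              f"(k={fit.k:.4f}); abs-lobe signed-recon rel L1 {ab.rel_l1_error:.4f}")
    out = root / "src/lobehf/basisdata" / basis._LOBE_CACHE_FILE
    out.write_text(json.dumps(basis._lobe_cache, indent=1))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
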