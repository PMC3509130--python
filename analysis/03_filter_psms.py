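#!/usr/bin/env python
"""Filter PSM tables and report the target-decoy FDR.

Applies the spectrum-level acceptance rules (fully tryptic, XCorr
1.8/2.5/3.5 by charge, deltCN >= 0, <= 4 missed cleavages, -10 <= ppm <= 10),
estimates the empirical FDR as 2D/(T+D), and writes the accepted table and an
FDR report.
"""

from pathlib import Path

from mproteo import io as mio
from mproteo.psm import FilterPolicy, estimate_fdr, filter_psms

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    psms = mio.read_psms(OUT / "psms.tsv")
    accepted, stats = filter_psms(psms, FilterPolicy(), "mm")
    mio.write_psms(OUT / "psms_accepted.tsv", accepted)
    report = estimate_fdr(accepted)
    mio.write_json(OUT / "fdr_report.json", {"stats": stats, "fdr": report})

    print(f"accepted {stats['accepted']}/{stats['input']} PSMs")
    for reason in ("tryptic", "miscleavage", "xcorr", "deltcn", "ppm"):
        print(f"  rejected by {reason}: {stats[f'rejected_{reason}']}")
    print(f"pooled empirical FDR: {100 * report['pooled']:.2f}% "
          f"(study threshold: <= 2.0%)")


if __name__ == "__main__":
    main()
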