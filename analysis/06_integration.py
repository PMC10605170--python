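"""Integrate GSEA scores with promoter-proximal peak signal per factor.

Combines NES x -log10(FDR) per factor and Spearman-correlates it with the
mean peak score at the focal promoter (window center +/- 1 kb), ranking
factors by combined regulatory evidence. Writes results/integration.tsv.

    python analysis/06_integration.py
"""

import numpy as np
import pandas as pd

from regscan import io
from regscan.intervals import GenomicInterval
from regscan.pipeline import _load_peaks
from regscan.similarity import gsea_signal_integration

from _study import RESULTS, STUDY_DIR


def main() -> None:
    gsea = pd.read_csv(RESULTS / "gsea.tsv", sep="\t", index_col=0)
    track = pd.read_csv(RESULTS / "bin_track.tsv", sep="\t")
    center = (int(track["start"].min()) + int(track["end"].max())) // 2
    promoter = GenomicInterval(track["chrom"].iloc[0], center - 1000, center + 1000)

    experiments = _load_peaks(str(STUDY_DIR / "peak_manifest.tsv"), None)
    signal: dict[str, list[float]] = {}
    for exp in experiments:
        m = (exp.starts < promoter.end) & (exp.ends > promoter.start)
        if m.any():
            signal.setdefault(exp.factor, []).extend(exp.scores[m].tolist())
    promoter_signal = pd.Series({f: float(np.mean(v)) for f, v in signal.items()})

    rho, p, table = gsea_signal_integration(gsea, promoter_signal)
    table.to_csv(RESULTS / "integration.tsv", sep="\t", index_label="factor",
                 float_format=io.FLOAT_FORMAT)
    print(f"promoter {promoter}; {len(table)} factors with both GSEA and signal")
    print(f"Spearman rho(GSEA score, promoter signal) = {rho:.2f} (p = {p:.3g})")
    print("factors ranked by combined GSEA score:")
    print(table.head(5).round(3).to_string())


if __name__ == "__main__":
    main()
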