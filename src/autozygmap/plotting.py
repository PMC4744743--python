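"""Static per-chromosome visualisation of autozygous regions and markers.

A convenience plot, not a faithful reproduction of any interactive display:
one horizontal track per sample per chromosome, with autozygous regions as
filled rectangles (affected samples in blue, unaffected in pink) and
optional marker states as thin vertical ticks (homozygous black,
heterozygous yellow).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .autozygosity import M_HET, M_HOM, AutozygousRegion, MarkerSeq


def plot_regions(
    regions_by_sample: Mapping[str, Sequence[AutozygousRegion]],
    chrom_lengths: Mapping[str, int],
    path: str,
    status_by_sample: Mapping[str, str] | None = None,
    marker_seqs: Mapping[str, Mapping[str, MarkerSeq]] | None = None,
) -> None:
    status_by_sample = status_by_sample or {}
    samples = sorted(regions_by_sample)
    chroms = list(chrom_lengths)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.2 + 0.5 * len(samples) * len(chroms)),
        squeeze=False,
    )
    for ci, chrom in enumerate(chroms):
        ax = axes[ci][0]
        for si, sid in enumerate(samples):
            y = len(samples) - si - 1
            if marker_seqs and sid in marker_seqs and chrom in marker_seqs[sid]:
                seq = marker_seqs[sid][chrom]
                hom = seq.positions[seq.states == M_HOM]
                het = seq.positions[seq.states == M_HET]
                ax.vlines(hom, y + 0.05, y + 0.45, colors="black", lw=0.3)
                ax.vlines(het, y + 0.05, y + 0.45, colors="gold", lw=0.3)
            color = "#9ecae9" if status_by_sample.get(sid) == "affected" else "#f4b8c8"
            for r in regions_by_sample[sid]:
                if r.chrom != chrom:
                    continue
                ax.axhspan(y + 0.5, y + 0.95, xmin=r.start / chrom_lengths[chrom],
                           xmax=r.end / chrom_lengths[chrom], color=color)
        ax.set_xlim(0, chrom_lengths[chrom])
        ax.set_ylim(0, len(samples))
        ax.set_yticks([len(samples) - si - 0.5 for si in range(len(samples))])
        ax.set_yticklabels(samples, fontsize=7)
        ax.set_title(f"chromosome {chrom}", fontsize=9)
        ax.set_xlabel("position (bp)", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
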