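"""Lane deconvolution: barcode demultiplexing and adapter trimming.

In a genotype-by-sequencing experiment 96 (sometimes 384) barcoded samples
are pooled in one Illumina lane. This module splits a lane FASTQ into one
file per sample by exact barcode-prefix matching (the longest matching
barcode wins when one barcode is a prefix of another), removes the barcode,
and trims 3'-end adapter read-through: the first occurrence of a short
adapter tag (default ``AGATCG``, the leading 6-mer of the common adapter) is
searched in each read and the read is truncated to the base before it.
Reads that match no barcode, or whose sequence is empty after trimming, are
routed to a rejects file.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "BarcodeMap",
    "DEFAULT_ADAPTER_TAG",
    "LaneReport",
    "UNASSIGNED",
    "assign_read",
    "demultiplex_lane",
    "trim_adapter",
]

DEFAULT_ADAPTER_TAG = "AGATCG"

#: Sentinel returned for reads matching no barcode.
UNASSIGNED = None


class BarcodeMap:
    """Barcode sequence -> sample identifier map.

    Barcodes are non-empty strings over ACGT and must be unique; several
    barcodes may map to the same sample. Lookup is exact-prefix with a
    longest-match tie-break, so one barcode being a prefix of another is
    allowed and unambiguous.
    """

    def __init__(self, entries: dict[str, str]):
        if not entries:
            raise ValueError("empty barcode map")
        for barcode in entries:
            if not barcode or set(barcode) - set("ACGT"):
                raise ValueError(f"invalid barcode {barcode!r}")
        self.entries = dict(entries)
        # probe lengths longest-first so the longest matching barcode wins
        self._lengths = sorted({len(b) for b in entries}, reverse=True)

    @classmethod
    def from_file(cls, path) -> "BarcodeMap":
        """Read a 2-column tab-separated file: barcode <TAB> sample."""
        entries: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'barcode<TAB>sample'"
                    )
                barcode, sample = parts[0].strip().upper(), parts[1].strip()
                if barcode in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate barcode {barcode}")
                entries[barcode] = sample
        return cls(entries)

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def match(self, read_sequence: str) -> tuple[str, str] | None:
        """Return ``(barcode, sample)`` for the longest barcode that is an
        exact prefix of the read, or ``None``."""
        for length in self._lengths:
            sample = self.entries.get(read_sequence[:length])
            if sample is not None:
                return read_sequence[:length], sample
        return None


def assign_read(read_sequence: str, barcodes: BarcodeMap):
    """Sample identifier whose barcode prefixes the read, or ``UNASSIGNED``."""
    hit = barcodes.match(read_sequence)
    return UNASSIGNED if hit is None else hit[1]


def trim_adapter(
    sequence: str, qualities: str | None = None, tag: str = DEFAULT_ADAPTER_TAG
) -> tuple[str, str | None, bool]:
    """Truncate a read at the first occurrence of the adapter tag.

    Returns ``(sequence, qualities, trimmed)``; qualities are truncated in
    lockstep. Idempotent, and the output is always a prefix of the input.
    """
    if len(tag) < 4:
        raise ValueError("adapter tag must be at least 4 bp")
    cut = sequence.find(tag)
    if cut < 0:
        return sequence, qualities, False
    return sequence[:cut], qualities[:cut] if qualities is not None else None, True


@dataclass
class LaneReport:
    """Per-lane demultiplexing accounting.

    The partition invariant ``sum(assigned per sample) + unassigned +
    discarded == total_reads`` always holds; ``discarded`` counts assigned
    reads whose post-trim sequence fell below the minimum length.
    """

    total_reads: int = 0
    unassigned: int = 0
    discarded: int = 0
    assigned: dict[str, int] = field(default_factory=dict)
    trimmed: dict[str, int] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def trimmed_fraction(self) -> float:
        n_kept_or_cut = self.n_assigned + self.discarded
        if n_kept_or_cut == 0:
            return 0.0
        return (sum(self.trimmed.values())) / n_kept_or_cut

    def to_text(self) -> str:
        lines = [
            "sample\tassigned\ttrimmed",
            *(
                f"{s}\t{n}\t{self.trimmed.get(s, 0)}"
                for s, n in sorted(self.assigned.items())
            ),
            f"#total\t{self.total_reads}",
            f"#unassigned\t{self.unassigned}",
            f"#discarded\t{self.discarded}",
            f"#trimmed_fraction\t{self.trimmed_fraction:.6f}",
        ]
        return "\n".join(lines) + "\n"


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t"))


def demultiplex_lane(
    fastq_in,
    barcodes: BarcodeMap,
    out_dir,
    tag: str = DEFAULT_ADAPTER_TAG,
    min_read_length: int = 1,
) -> LaneReport:
    """Split a lane FASTQ (plain or gzip) into per-sample FASTQ files.

    Each assigned read has its barcode removed and is adapter-trimmed before
    writing. Unassigned reads and reads shorter than ``min_read_length``
    after trimming go to ``<out_dir>/rejects.fastq``; a tab-separated report
    is written to ``<out_dir>/demux_report.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = LaneReport(assigned={s: 0 for s in barcodes.samples})
    handles = {
        s: open(out_dir / f"{s}.fastq", "w") for s in barcodes.samples
    }
    rejects = open(out_dir / "rejects.fastq", "w")
    try:
        with _open_text(fastq_in) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                report.total_reads += 1
                hit = barcodes.match(seq)
                if hit is None:
                    report.unassigned += 1
                    rejects.write(f"@{title}\n{seq}\n+\n{qual}\n")
                    continue
                barcode, sample = hit
                seq2, qual2, trimmed = trim_adapter(
                    seq[len(barcode):], qual[len(barcode):], tag
                )
                if trimmed:
                    report.trimmed[sample] = report.trimmed.get(sample, 0) + 1
                if len(seq2) < min_read_length:
                    report.discarded += 1
                    rejects.write(f"@{title}\n{seq}\n+\n{qual}\n")
                    continue
                report.assigned[sample] += 1
                handles[sample].write(f"@{title}\n{seq2}\n+\n{qual2}\n")
    finally:
        for handle in handles.values():
            handle.close()
        rejects.close()
    (out_dir / "demux_report.tsv").write_text(report.to_text())
    return report
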