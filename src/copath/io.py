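"""Plain-text readers and writers for the package's data structures.

All formats are delimited text: motif sequences and community maps as
TSV, EEG/EMG/movement recordings as TSV with a sampling-rate header
line, hypnograms and event tables as TSV, sweeps as two-column (t_ms,
mV) tables, and count matrices as MatrixMarket (.mtx) plus feature /
barcode TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .behavior.sequences import MotifSequence
from .ephys import Sweep
from .sleep.core import Hypnogram, Recording


# -- motif sequences ---------------------------------------------------------

def write_motif_sequence(seq: MotifSequence, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# animal_id: {seq.animal_id}\n")
        fh.write(f"# genotype: {seq.genotype}\n")
        fh.write(f"# frame_rate: {seq.frame_rate}\n")
        fh.write("frame\tmotif_id\n")
        for i, m in enumerate(seq.labels):
            fh.write(f"{i}\t{m}\n")


def read_motif_sequence(path) -> MotifSequence:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    labels = list(table["motif_id"])
    return MotifSequence(
        animal_id=meta.get("animal_id", path.stem),
        genotype=meta.get("genotype", ""),
        labels=labels,
        frame_rate=float(meta.get("frame_rate", 30.0)),
    )


def read_community_map(path) -> dict:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("community map needs two columns (motif, community)")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


# -- recordings and hypnograms ----------------------------------------------

def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate: {rec.sampling_rate}\n")
        fh.write("eeg\temg\tmovement\n")
        np.savetxt(fh, np.column_stack([rec.eeg, rec.emg, rec.movement]),
                   fmt="%.6g", delimiter="\t")


def read_recording(path) -> Recording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# sampling_rate:"):
            raise ValueError("missing '# sampling_rate:' header line")
        fs = float(header.split(":")[1])
        table = pd.read_csv(fh, sep="\t")
    return Recording(eeg=table["eeg"].to_numpy(),
                     emg=table["emg"].to_numpy(),
                     movement=table["movement"].to_numpy(),
                     sampling_rate=fs)


def write_hypnogram(h: Hypnogram, path) -> None:
    pd.DataFrame({"epoch": range(len(h)), "state": h.states}).to_csv(
        path, sep="\t", index=False)


def read_hypnogram(path, epoch_len: float = 10.0) -> Hypnogram:
    table = pd.read_csv(path, sep="\t")
    return Hypnogram(states=list(table["state"]), epoch_len=epoch_len)


# -- sweeps ------------------------------------------------------------------

def write_sweep(s: Sweep, path) -> None:
    pd.DataFrame({"t_ms": s.time, "mV": s.voltage}).to_csv(
        path, sep="\t", index=False)


def read_sweep(path, stimulus_time: float = 0.0,
               intensity: float | None = None) -> Sweep:
    table = pd.read_csv(path, sep="\t")
    return Sweep(time=table["t_ms"].to_numpy(),
                 voltage=table["mV"].to_numpy(),
                 stimulus_time=stimulus_time, intensity=intensity)


# -- count matrices ----------------------------------------------------------

def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write a gene x cell (or gene x sample) matrix as MTX + TSV sidecars."""
    prefix = Path(prefix)
    scio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        prefix.parent / (prefix.name + ".features.tsv"),
        sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(
        prefix.parent / (prefix.name + ".barcodes.tsv"),
        sep="\t", index=False, header=False)


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scio.mmread(str(prefix.with_suffix(".mtx")))
    features = pd.read_csv(prefix.parent / (prefix.name + ".features.tsv"),
                           sep="\t", header=None)[0]
    barcodes = pd.read_csv(prefix.parent / (prefix.name + ".barcodes.tsv"),
                           sep="\t", header=None)[0]
    return pd.DataFrame(np.asarray(mat.todense()), index=features,
                        columns=barcodes)
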