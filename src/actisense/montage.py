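"""64-channel 10-10 electrode labels (Biosemi ActiveTwo ordering)."""

BIOSEMI64 = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)


def channel_labels(n_channels: int) -> list[str]:
    """First ``n_channels`` labels of the 64-channel 10-10 montage."""
    if n_channels < 1 or n_channels > len(BIOSEMI64):
        raise ValueError(f"n_channels must be in [1, {len(BIOSEMI64)}]")
    return list(BIOSEMI64[:n_channels])
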