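"""Run configuration: every tunable parameter of the pipeline, with defaults.

A flat key=value text file may override any subset of fields; the effective
configuration is logged to stderr at run start.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .core import log


@dataclass
class RunConfig:
    rng_seed: int = 0

    # core_model_io
    min_gap_run: int = 10          # min consecutive Ns called an assembly gap

    # repeat decomposition / profiling
    min_units: int = 4             # shortest run called a repeat region
    max_consecutive_mismatch: int = 1
    mismatch_frac: float = 0.10
    predominance_threshold: float = 0.30

    # synthetic locus generation
    flank5_len: int = 300
    flank3_len: int = 300
    flank_gc: float = 0.45
    leader_len: int = 51           # in-frame coding leader 5' of the repeats
    intergenic_min: int = 5000
    intergenic_max: int = 20000
    neighbor_genes: bool = True
    neighbor_len: int = 1000
    stop_codon: str = "TAA"
    flank_keep: int = 150          # bases kept each side when degrading to scaffold

    # read classification
    max_period: int = 9
    repeat_threshold: float = 0.55
    min_read_len: int = 50

    # read simulation
    read_len: int = 400
    coverage: float = 20.0
    insert_mean: float = 3000.0
    insert_sd: float = 300.0

    # repeat masking emulation
    mask_max_period: int = 6       # perfect arrays of period <= this get masked
    mask_min_len: int = 12

    # gene finding
    min_units_stub: int = 3
    onset_slack: int = 5

    # synteny mapping
    seed_k: int = 20
    max_seed_occ: int = 10
    identity_window: int = 100
    min_identity: float = 0.70
    min_block_len: int = 100

    # demo pipeline
    demo_n_genes: int = 7
    demo_units: tuple[int, ...] = (20, 35, 50, 141, 30, 45, 25)
    demo_split: int = 5            # genes on scaffold 1; rest on scaffold 2

    def override_from_file(self, path: str | Path) -> "RunConfig":
        """Apply key=value overrides from a flat config file."""
        text = Path(path).read_text()
        types = {f.name: f.type for f in fields(self)}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or not hasattr(self, key):
                raise ValueError(f"config line {lineno}: unknown entry {line!r}")
            current = getattr(self, key)
            if isinstance(current, bool):
                setattr(self, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(self, key, int(value))
            elif isinstance(current, float):
                setattr(self, key, float(value))
            elif isinstance(current, tuple):
                setattr(self, key, tuple(int(v) for v in value.split(",")))
            else:
                setattr(self, key, value)
        del types
        return self

    def log_effective(self) -> None:
        for f in fields(self):
            log("INFO", f"config {f.name} = {getattr(self, f.name)}")
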