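"""Small shared helpers: seed derivation and output manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed.

    Hashing (base seed, stage name) keeps stages reproducible in isolation
    and independent of execution order; the result fits in 31 bits.
    """
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable config dict."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seeds: dict[str, int]) -> None:
    """Echo the run's configuration and derived seeds next to its outputs.

    Deliberately contains nothing run-dependent beyond the config itself,
    so identical runs produce byte-identical manifests.
    """
    out = Path(out_dir)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": config,
                "config_hash": config_hash(config),
                "seeds": seeds,
            },
            fh,
            indent=1,
            default=str,
        )
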