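"""Fetch experimental structures from the RCSB PDB (network required).

Used only by workflows that compare against published crystal structures;
everything else in the package runs fully offline.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb"]

_URL = "https://files.rcsb.org/download/{code}.pdb"


def fetch_pdb(code: str, cache_dir: str | Path = ".pdb_cache",
              timeout: float = 20.0) -> Path:
    """Download (or reuse a cached copy of) a PDB entry; returns the path.

    Raises ``ConnectionError`` when the archive is unreachable.
    """
    code = code.lower()
    if len(code) != 4 or not code.isalnum():
        raise ValueError(f"not a PDB id: {code!r}")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{code}.pdb"
    if target.exists():
        return target
    url = _URL.format(code=code.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError) as exc:
        raise ConnectionError(f"cannot fetch {code} from {url}: {exc}") from exc
    target.write_bytes(data)
    return target
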