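"""Optional KEGG download helper.

Fetching is network-isolated from the rest of the package: everything
else parses local KGML files, so the test suite and any offline run
never touch the network.  Uses the KEGG REST API (no key required).
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.request
from pathlib import Path

logger = logging.getLogger(__name__)

KEGG_LIST_URL = "https://rest.kegg.jp/list/pathway/{organism}"
KEGG_GET_URL = "https://rest.kegg.jp/get/{pathway}/kgml"


def _fetch(url: str, retries: int = 2, delay: float = 1.0) -> str:
    last: Exception | None = None
    for attempt in range(retries + 1):
        try:
            with urllib.request.urlopen(url, timeout=30) as response:
                return response.read().decode()
        except (urllib.error.URLError, TimeoutError) as exc:
            last = exc
            if attempt < retries:
                time.sleep(delay)
    raise ConnectionError(f"KEGG request failed after {retries + 1} attempts: {url}") from last


def list_pathways(organism: str) -> list[str]:
    """Pathway ids (e.g. ``hsa04066``) for an organism code."""
    text = _fetch(KEGG_LIST_URL.format(organism=organism))
    ids = []
    for line in text.strip().splitlines():
        token = line.split("\t")[0].strip()
        if token.startswith("path:"):
            token = token[5:]
        if token:
            ids.append(token)
    return ids


def fetch_kegg(
    organism: str,
    out_dir: str | Path,
    pathway_ids: list[str] | None = None,
) -> list[Path]:
    """Download KGML files for an organism; write a listing manifest.

    All files are fetched before the manifest is written, so a failed
    run leaves no (partial) manifest behind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = pathway_ids if pathway_ids is not None else list_pathways(organism)
    written: list[Path] = []
    for pid in ids:
        xml = _fetch(KEGG_GET_URL.format(pathway=pid))
        path = out / f"{pid}.kgml"
        path.write_text(xml)
        written.append(path)
        logger.info("fetched %s", pid)
    manifest = out / "kegg_manifest.json"
    manifest.write_text(
        json.dumps({"organism": organism, "pathways": [p.name for p in written]}, indent=2)
        + "\n"
    )
    return written
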