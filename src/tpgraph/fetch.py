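"""Download the pinned source tables from a Zenodo record.

The readers in :mod:`tpgraph.tables_io` always take local paths; this
helper is the only network-touching code and is invoked explicitly
(``tpgraph ingest --fetch-zenodo``).  It resolves a DOI or record id via
the Zenodo REST API and downloads the two source CSV files.
"""

from __future__ import annotations

import json
import re
import urllib.parse
import urllib.request
from pathlib import Path

__all__ = ["fetch_zenodo", "SOURCE_FILENAMES", "DEFAULT_DOI"]

#: DOI of the versioned "transformations" deposition the tool consumes
DEFAULT_DOI = "10.5281/zenodo.17682349"

SOURCE_FILENAMES = (
    "Transformations_CID_Info_all.csv",
    "PubChem_all_transformations_wExtraInfo.csv",
)

_API = "https://zenodo.org/api/records"


def _get_json(url: str) -> dict:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return json.load(resp)


def fetch_zenodo(
    doi: str = DEFAULT_DOI,
    outdir: str | Path = ".",
    filenames: tuple[str, ...] = SOURCE_FILENAMES,
) -> dict[str, Path]:
    """Download ``filenames`` from the Zenodo record behind ``doi``.

    Returns {filename: local path}.  Existing files are not re-downloaded.
    Raises ``URLError``/``LookupError`` when the host is unreachable or
    the record lacks a requested file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = re.search(r"zenodo\.(\d+)", doi)
    if m:
        record = _get_json(f"{_API}/{m.group(1)}")
    else:
        hits = _get_json(f"{_API}?q=doi:%22{urllib.parse.quote(doi)}%22")["hits"]["hits"]
        if not hits:
            raise LookupError(f"no Zenodo record found for DOI {doi}")
        record = hits[0]
    files = {f["key"]: f for f in record.get("files", [])}
    out: dict[str, Path] = {}
    for name in filenames:
        dest = outdir / name
        if not dest.exists():
            if name not in files:
                raise LookupError(f"record has no file named {name!r}")
            url = files[name]["links"]["self"]
            with urllib.request.urlopen(url, timeout=600) as resp:
                dest.write_bytes(resp.read())
        out[name] = dest
    return out
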