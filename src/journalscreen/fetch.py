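"""Optional, thin NCBI E-utilities client for harvesting article metadata.

Never exercised by the test suite; requires the ``fetch`` extra
(biopython) and network access.  Responses are cached on disk and requests
are rate-limited to stay within NCBI's posted limits.  Large-scale
harvesting orchestration (retries, backfill) is out of scope.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

# Template reconstructing the journal-eligibility query against the NLM
# catalog: MEDLINE journals carrying at least one Broad Subject Term and
# currently indexed.  Callers substitute the Broad Subject Term list.
NLM_CATALOG_QUERY_TEMPLATE = (
    "({terms}) AND currentlyindexed[All] AND medline[subset]"
)

_MIN_INTERVAL_S = 0.34  # <=3 requests/s without an API key


def fetch_pubmed_xml(
    term: str,
    email: str,
    mindate: str = "2015/01/01",
    maxdate: str = "2019/12/31",
    retmax: int = 10_000,
    cache_dir: str | Path | None = None,
    api_key: str | None = None,
) -> bytes:
    """Fetch ``PubmedArticleSet`` XML for a PubMed query (esearch + efetch).

    Returns the raw XML bytes, suitable for ``parse_medline_xml``.  With a
    cache directory, identical queries are served from disk.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = hashlib.sha256(
            f"{term}|{mindate}|{maxdate}|{retmax}".encode()
        ).hexdigest()
        cache_file = cache_dir / f"{key}.xml"
        if cache_file.exists():
            return cache_file.read_bytes()

    from Bio import Entrez  # lazy: only needed for live fetching

    Entrez.email = email
    if api_key:
        Entrez.api_key = api_key

    with Entrez.esearch(
        db="pubmed", term=term, mindate=mindate, maxdate=maxdate,
        datetype="pdat", retmax=retmax,
    ) as handle:
        ids = Entrez.read(handle)["IdList"]
    time.sleep(_MIN_INTERVAL_S)
    if not ids:
        data = b"<?xml version='1.0'?><PubmedArticleSet></PubmedArticleSet>"
    else:
        with Entrez.efetch(
            db="pubmed", id=",".join(ids), rettype="xml", retmode="xml"
        ) as handle:
            data = handle.read()
        time.sleep(_MIN_INTERVAL_S)

    if cache_dir is not None:
        cache_file.write_bytes(data)
    return data
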