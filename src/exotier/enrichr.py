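"""Thin client for the EnrichR gene-set enrichment API.

This is the only networked component of the package.  The gene list sent out
contains only genes with at least one variant above the pathogenic posterior
threshold.  The HTTP transport is injectable so tests run fully offline, and
any network failure degrades to a warning — the rest of the reports are
unaffected.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
from typing import Callable

import pandas as pd

from .exceptions import EnrichrUnavailable

DEFAULT_LIBRARY = "GO_Biological_Process_2018"
BASE_URL = "https://maayanlab.cloud/Enrichr"

RESULT_COLUMNS = [
    "Rank", "Term", "P_value", "Z_score", "Combined_score", "Genes",
    "Adjusted_p_value", "Old_p_value", "Old_adjusted_p_value",
]

Transport = Callable[[str, bytes | None], bytes]


def _urllib_transport(url: str, data: bytes | None = None) -> bytes:
    with urllib.request.urlopen(url, data=data, timeout=30) as response:
        return response.read()


class EnrichrClient:
    """Minimal addList + enrich round trip against the EnrichR API."""

    def __init__(self, base_url: str = BASE_URL, transport: Transport | None = None):
        self.base_url = base_url.rstrip("/")
        self.transport = transport or _urllib_transport

    def enrich(self, genes: list[str], library: str = DEFAULT_LIBRARY) -> pd.DataFrame:
        """Submit a gene list and return the ranked term table for one library."""
        if not genes:
            raise EnrichrUnavailable("empty gene list; nothing to submit")
        try:
            payload = urllib.parse.urlencode(
                {"list": "\n".join(genes), "description": "exotier pathogenic genes"}
            ).encode()
            added = json.loads(self.transport(f"{self.base_url}/addList", payload))
            user_list_id = added["userListId"]
            raw = self.transport(
                f"{self.base_url}/enrich?userListId={user_list_id}"
                f"&backgroundType={urllib.parse.quote(library)}",
                None,
            )
            results = json.loads(raw)
        except EnrichrUnavailable:
            raise
        except Exception as exc:  # network / JSON / schema failures all degrade alike
            raise EnrichrUnavailable(f"EnrichR request failed: {exc}") from exc
        rows = results.get(library, [])
        table = pd.DataFrame(
            [dict(zip(RESULT_COLUMNS, row)) for row in rows], columns=RESULT_COLUMNS
        )
        return table
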