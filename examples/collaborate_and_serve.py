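"""Projects, roles, co-annotation and a shareable session over HTTP.

Starts the WSGI service on a free port, stores a view session, fetches it
back through its share URL, and shows role-gated annotation with history.
"""

import json
import threading
import urllib.request

from omicview.collab import AuthorizationError, CollabStore
from omicview.linkage import ViewSession, serialize_session
from omicview.service import EngineContext, serve
from omicview.simulate import SyntheticGenomeSpec, make_assembly

store = CollabStore()  # in-memory; pass a path for persistence
store.add_user("ana", "Ana", "pw1")
store.add_user("ben", "Ben", "pw2")
store.create_project("maize", "Maize multiome", owner="ana", species="Zea mays")
store.set_role("maize", "ana", "ben", "viewer")

r1 = store.annotate("maize", "ana", "cluster:3", "cell_type_label", "mesophyll")
r2 = store.annotate("maize", "ana", "cluster:3", "cell_type_label", "bundle sheath")
latest = store.latest_annotation("maize", "cluster:3", "cell_type_label")
print(f"annotation revisions {r1} -> {r2}; latest = {latest.value!r} "
      f"(last writer wins, full history kept)")
try:
    store.annotate("maize", "ben", "cluster:3", "cell_type_label", "nope")
except AuthorizationError as e:
    print(f"viewer write rejected: {e}")

ctx = EngineContext(assembly=make_assembly(SyntheticGenomeSpec()), store=store)
srv, port = serve(ctx, port=0)
t = threading.Thread(target=srv.serve_forever, daemon=True)
t.start()
print(f"service on port {port}")

session = ViewSession(session_id="demo",
                      view_states=[{"chrom": "chr1", "start": 0, "end": 100_000,
                                    "view_width": 1200}])
req = urllib.request.Request(f"http://127.0.0.1:{port}/session",
                             data=serialize_session(session).encode(),
                             headers={"Content-Type": "application/json"})
doc = json.loads(urllib.request.urlopen(req).read())
print(f"share URL: {doc['url']}  (resolves to the same session after restart)")
back = json.loads(urllib.request.urlopen(
    f"http://127.0.0.1:{port}{doc['url']}").read())
print(f"fetched session id: {back['session_id']}")
srv.shutdown()
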