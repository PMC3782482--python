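"""Fit a single fly's pose from its silhouette.

Renders one teardrop silhouette at a known position and heading, then runs
the moment-based ellipse fit and the Harris-corner head/tail assignment.
"""

import math

import numpy as np

from flychain import synthscene, tracking

position, heading = (41.4, 200.3), math.radians(30)
mask = synthscene.render_fly(position, heading, synthscene.FlyShape())
silhouette = tracking.Silhouette(pixels=np.argwhere(mask))

pose = tracking.fit_body_ellipse(silhouette)
pose = tracking.assign_head_tail(silhouette, pose)

true = synthscene.TruePose(position=np.asarray(position), heading_rad=heading)
print(f"true centroid  ({position[0]:.1f}, {position[1]:.1f}),"
      f" heading {math.degrees(heading):.0f} deg")
print(f"fit centroid   ({pose.centroid[0]:.1f}, {pose.centroid[1]:.1f})")
print(f"axes           {pose.major_axis_len:.1f} x {pose.minor_axis_len:.1f} px")
print(f"orientation    {math.degrees(pose.orientation):.1f} deg (mod 180)")
print(f"head at        ({pose.H[0]:.1f}, {pose.H[1]:.1f}); "
      f"true head ({true.H[0]:.1f}, {true.H[1]:.1f})")
print(f"head error     {np.linalg.norm(pose.H - true.H):.2f} px")
# The abdominal tip is sharper than the head, so the axis endpoint with the
# larger Harris corner response is labelled tail; the other is the head.
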