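"""Recover a static 30-degree tilt from simulated six-axis IMU data.

Generates a noisy gyro/accelerometer stream for a sensor held at a constant
30-degree roll, runs the complementary quaternion filter over it, and prints
the recovered roll angle.  The filter starts at the identity orientation, so
the printed trace shows the estimate converging onto the true tilt.
"""

import math

from wearmotion import FusionGains, TrajectorySpec, generate_imu_trajectory, solve_stream

TILT_DEG = 30.0

spec = TrajectorySpec(
    roll=lambda t: math.radians(TILT_DEG),
    duration=10.0,
    dt=0.01,
    gyro_noise_sd=0.002,   # rad/s
    accel_noise_sd=0.005,  # fraction of gravity magnitude
    seed=13,
)
stream, truth = generate_imu_trajectory(spec)
_, eulers = solve_stream(stream, FusionGains(kp=2.0, ki=0.005, half_t=spec.dt / 2))

print(f"true roll: {TILT_DEG:.2f} deg; estimates while converging:")
for k in (9, 49, 99, 499, 999):
    print(f"  after {k + 1:4d} steps: roll = {math.degrees(eulers[k].roll):7.3f} deg")
err = math.degrees(abs(eulers[-1].roll - math.radians(TILT_DEG)))
print(f"final absolute error: {err:.3f} deg")
print("The PI gravity correction pulls the gyro-integrated attitude onto the")
print("accelerometer's gravity direction; sub-degree error means the fusion")
print("has locked onto the true tilt despite sensor noise.")
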