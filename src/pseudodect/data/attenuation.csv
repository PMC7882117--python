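# Photon mass attenuation coefficients (cm^2/g) on a coarse standard energy grid,
# with duplicated points straddling K-edges (iodine 33.17 keV, tin 29.20 keV).
# Values follow the NIST/XCOM tabulations for these materials; the package
# interpolates log-log onto a 1-keV working grid (10-150 keV).
material,density_g_cm3,energy_kev,mu_over_rho_cm2_g
water,1.000,10,5.329
water,1.000,15,1.673
water,1.000,20,0.8096
water,1.000,30,0.3756
water,1.000,40,0.2683
water,1.000,50,0.2269
water,1.000,60,0.2059
water,1.000,80,0.1837
water,1.000,100,0.1707
water,1.000,150,0.1505
air,0.001205,10,5.120
air,0.001205,15,1.614
air,0.001205,20,0.7779
air,0.001205,30,0.3538
air,0.001205,40,0.2485
air,0.001205,50,0.2080
air,0.001205,60,0.1875
air,0.001205,80,0.1662
air,0.001205,100,0.1541
air,0.001205,150,0.1356
acrylic,1.190,10,3.357
acrylic,1.190,15,1.101
acrylic,1.190,20,0.5714
acrylic,1.190,30,0.3032
acrylic,1.190,40,0.2350
acrylic,1.190,50,0.2074
acrylic,1.190,60,0.1924
acrylic,1.190,80,0.1751
acrylic,1.190,100,0.1641
acrylic,1.190,150,0.1456
aluminum,2.699,10,26.23
aluminum,2.699,15,7.955
aluminum,2.699,20,3.441
aluminum,2.699,30,1.128
aluminum,2.699,40,0.5685
aluminum,2.699,50,0.3681
aluminum,2.699,60,0.2778
aluminum,2.699,80,0.2018
aluminum,2.699,100,0.1704
aluminum,2.699,150,0.1378
iodine,4.933,10,162.0
iodine,4.933,15,55.00
iodine,4.933,20,25.43
iodine,4.933,30,8.561
iodine,4.933,33.169,6.553
iodine,4.933,33.170,36.03
iodine,4.933,40,22.10
iodine,4.933,50,12.32
iodine,4.933,60,7.579
iodine,4.933,80,3.510
iodine,4.933,100,1.942
iodine,4.933,150,0.6978
tin,7.310,10,140.9
tin,7.310,15,47.00
tin,7.310,20,21.65
tin,7.310,29.200,7.760
tin,7.310,29.201,42.70
tin,7.310,30,40.52
tin,7.310,40,19.42
tin,7.310,50,10.75
tin,7.310,60,6.551
tin,7.310,80,3.029
tin,7.310,100,1.725
tin,7.310,150,0.6514
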