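year,cocoa_price,cocoa_yield,maize_price,maize_yield,banana_price,banana_yield,soybean_price,soybean_yield,rice_price,rice_yield
1970,381.1,0.2,54.0,0.9,24.3,15.0,144.0,1.0,68.2,2.7
1971,364.5,0.3,101.2,0.7,20.2,15.2,76.4,1.1,60.1,3.5
1972,383.6,0.3,116.7,0.7,20.8,15.1,156.7,1.2,69.4,2.1
1973,791.8,0.3,162.9,0.9,26.3,15.4,187.2,1.3,84.7,2.8
1974,931.4,0.4,207.7,0.9,27.8,17.6,368.1,1.4,126.0,2.6
1975,1028.3,0.3,208.1,1.0,29.9,23.2,335.6,1.5,153.9,3.0
1976,1310.0,0.3,195.8,1.0,30.2,24.0,332.2,1.5,157.9,2.6
1977,1687.5,0.3,201.5,0.9,33.2,24.4,348.6,1.3,175.8,3.1
1978,2105.7,0.3,210.6,1.0,36.7,28.0,371.2,1.5,197.0,2.8
1979,2055.6,0.3,204.1,1.0,37.0,30.1,362.7,1.3,192.8,2.9
1980,1857.2,0.3,220.7,1.1,38.9,32.2,371.8,1.3,203.0,3.0
1981,1061.3,0.3,196.5,1.2,35.2,31.4,331.5,1.6,221.3,3.3
1982,822.5,0.4,129.7,1.5,36.3,30.7,207.4,1.8,153.0,2.9
1983,1286.8,0.2,204.7,1.1,19.9,27.7,242.1,1.4,165.9,2.9
1984,1522.9,0.3,192.5,1.3,30.1,27.7,185.2,1.7,201.1,3.1
1985,1395.5,0.5,180.5,1.6,22.6,30.2,251.5,1.8,234.8,2.7
1986,1313.3,0.3,137.0,1.0,27.7,20.7,305.0,1.9,225.1,2.5
1987,1563.4,0.2,158.9,0.9,33.6,20.0,284.9,1.8,122.7,2.8
1988,903.5,0.3,135.4,0.9,13.5,20.2,174.3,1.8,122.3,3.3
1989,891.7,0.3,134.7,1.1,115.9,19.7,266.6,1.9,181.4,3.1
1990,843.7,0.3,142.7,1.1,130.1,21.3,300.7,2.0,154.7,3.1
1991,686.2,0.3,254.2,1.1,147.3,20.9,274.3,1.9,122.0,3.0
1992,651.7,0.3,219.3,1.1,131.6,21.6,261.6,1.6,142.0,3.3
1993,725.3,0.3,455.1,1.2,126.8,21.7,263.7,1.8,139.2,3.5
1994,991.6,0.2,292.4,1.1,128.5,23.0,255.2,2.2,161.5,3.7
1995,907.7,0.2,452.8,1.1,116.5,23.7,246.1,1.1,169.2,3.3
1996,908.1,0.3,362.7,1.1,132.9,25.3,258.2,1.3,167.3,3.2
1997,1113.9,0.2,397.5,1.2,131.8,35.5,199.7,1.1,203.3,3.4
1998,1025.6,0.1,359.5,1.1,109.2,26.4,226.4,1.3,169.1,3.2
1999,913.7,0.3,270.8,1.2,164.0,33.0,141.0,1.8,157.0,3.5
2000,793.2,0.2,380.0,1.4,165.4,25.6,247.9,1.7,160.0,3.7
2001,816.5,0.2,473.0,0.8,146.0,26.5,227.0,1.9,136.0,3.6
2002,1397.7,0.2,450.0,1.4,160.0,24.4,256.0,2.0,130.0,3.9
2003,1379.5,0.3,345.0,1.7,153.0,27.6,229.0,1.7,149.0,3.9
2004,1175.2,0.3,308.0,1.9,124.0,27.1,242.0,1.7,226.0,4.2
2005,1242.7,0.3,345.0,2.1,116.0,27.7,188.0,2.0,191.0,3.9
2006,1491.9,0.3,355.8,1.9,117.3,29.3,271.9,1.2,165.4,4.2
2007,1901.6,0.2,398.4,2.3,138.0,30.4,358.7,1.7,238.2,4.4
2008,1543.7,0.3,853.3,2.2,133.1,31.1,469.3,1.6,291.8,4.1
2009,1803.1,0.3,855.0,2.2,149.8,35.3,488.3,1.7,262.5,4.0
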